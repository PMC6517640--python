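"""Volume QC, common-voxel masking and feature-matrix assembly.

Subjects whose volume has more than ``max_nan_fraction`` non-finite voxels
inside a scope mask are excluded (strict inequality); the common mask then
keeps only voxels finite in *every* remaining subject. Voxel ordering is a
fixed raster order with the first axis fastest-varying (Fortran order), so
feature columns and weight maps are bit-reproducible.

Infinities are treated the same as NaN throughout: both are non-usable
values from an upstream GLM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BrainMask",
    "FeatureMatrix",
    "default_scope_mask",
    "nan_fraction",
    "exclude_subjects",
    "build_common_mask",
    "assemble_features",
    "disassemble",
    "load_volume",
    "save_mask",
    "exclusion_report",
]

MAX_NAN_FRACTION = 0.15


@dataclass(frozen=True)
class BrainMask:
    """Boolean 3-D mask with a documented flat-index ordering.

    ``flat_indices`` are positions into ``ravel(order="F")`` of a volume on
    the same grid; column ``j`` of any feature matrix built with this mask
    corresponds to ``flat_indices[j]``.
    """

    array: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=bool)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        object.__setattr__(self, "array", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.array.shape

    @property
    def voxel_count(self) -> int:
        return int(self.array.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.array.ravel(order="F"))


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x masked-voxels values bound to a mask and subject order."""

    values: np.ndarray
    subject_ids: tuple
    mask: BrainMask

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if vals.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if vals.shape[1] != self.mask.voxel_count:
            raise ValueError("column count does not match mask voxel count")
        if not np.all(np.isfinite(vals)):
            raise ValueError("NaN/inf inside mask: mask and volumes are inconsistent")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def _check_same_grid(volumes: list[np.ndarray]) -> tuple[int, ...]:
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes do not share a grid: {sorted(shapes)}")
    (shape,) = shapes
    if len(shape) != 3:
        raise ValueError("volumes must be 3-D")
    return shape


def default_scope_mask(volumes: list[np.ndarray]) -> BrainMask:
    """Voxels finite and nonzero in at least half of the subjects.

    Stands in for a standard brain mask so the exclusion fraction is taken
    over plausibly-brain voxels rather than the whole bounding box.
    """
    _check_same_grid(volumes)
    stack = np.stack([np.asarray(v, dtype=float) for v in volumes])
    usable = np.isfinite(stack) & (stack != 0)
    return BrainMask(usable.sum(axis=0) >= (len(volumes) / 2.0))


def nan_fraction(volume: np.ndarray, scope_mask: BrainMask) -> float:
    """Fraction of scope-mask voxels that are non-finite in ``volume``."""
    if volume.shape != scope_mask.shape:
        raise ValueError("volume grid does not match scope mask")
    in_scope = np.asarray(volume, dtype=float)[scope_mask.array]
    if in_scope.size == 0:
        raise ValueError("scope mask is empty")
    return float(np.mean(~np.isfinite(in_scope)))


def exclude_subjects(
    volumes: list[np.ndarray],
    scope_mask: BrainMask | None = None,
    max_nan_fraction: float = MAX_NAN_FRACTION,
    subject_ids: list | None = None,
) -> tuple[list, list]:
    """Split subjects into kept / excluded by the strict >15%-missing rule.

    Returns ``(kept_ids, excluded_ids)`` preserving input order. A subject is
    excluded iff its non-finite fraction inside ``scope_mask`` is strictly
    greater than ``max_nan_fraction``.
    """
    if not 0.0 <= max_nan_fraction <= 1.0:
        raise ValueError("max_nan_fraction must lie in [0, 1]")
    _check_same_grid(volumes)
    if scope_mask is None:
        scope_mask = default_scope_mask(volumes)
    if subject_ids is None:
        subject_ids = list(range(len(volumes)))
    if len(subject_ids) != len(volumes):
        raise ValueError("subject_ids length does not match volumes")
    kept, excluded = [], []
    for sid, vol in zip(subject_ids, volumes):
        (excluded if nan_fraction(vol, scope_mask) > max_nan_fraction else kept).append(
            sid
        )
    return kept, excluded


def exclusion_report(
    volumes: list[np.ndarray],
    scope_mask: BrainMask,
    max_nan_fraction: float = MAX_NAN_FRACTION,
    subject_ids: list | None = None,
) -> pd.DataFrame:
    if subject_ids is None:
        subject_ids = list(range(len(volumes)))
    fracs = [nan_fraction(v, scope_mask) for v in volumes]
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "nan_fraction": fracs,
            "kept": [f <= max_nan_fraction for f in fracs],
        }
    )


def build_common_mask(
    volumes: list[np.ndarray], scope_mask: BrainMask | None = None
) -> BrainMask:
    """Mask of voxels inside the scope that are finite in every subject."""
    if not volumes:
        raise ValueError("kept subject set is empty")
    _check_same_grid(volumes)
    if scope_mask is None:
        scope_mask = default_scope_mask(volumes)
    common = scope_mask.array.copy()
    for vol in volumes:
        common &= np.isfinite(np.asarray(vol, dtype=float))
    if not common.any():
        raise ValueError("empty mask: no voxel is finite in all subjects")
    return BrainMask(common)


def assemble_features(
    volumes: list[np.ndarray],
    mask: BrainMask,
    subject_ids: list | None = None,
) -> FeatureMatrix:
    """Stack masked voxel values into a subjects x voxels matrix."""
    _check_same_grid(volumes)
    if subject_ids is None:
        subject_ids = list(range(len(volumes)))
    idx = mask.flat_indices
    rows = [np.asarray(v, dtype=float).ravel(order="F")[idx] for v in volumes]
    values = np.vstack(rows) if rows else np.empty((0, mask.voxel_count))
    return FeatureMatrix(values=values, subject_ids=tuple(subject_ids), mask=mask)


def disassemble(vector: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter a per-voxel vector back onto the 3-D grid (``fill`` outside)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (mask.voxel_count,):
        raise ValueError("vector length does not match mask voxel count")
    flat = np.full(int(np.prod(mask.shape)), fill, dtype=float)
    flat[mask.flat_indices] = vector
    return flat.reshape(mask.shape, order="F")


def load_volume(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_mask(mask: BrainMask, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.array.astype(np.uint8), np.eye(4)), str(path))
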