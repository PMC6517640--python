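"""Synthetic cohort generation.

Produces per-subject 3-D contrast volumes plus a subject table with the
statistical structure the decoding pipeline assumes: two groups (distressed /
healthy) with group-specific clinical-score distributions, zero-inflated
clinician-rated scales in the healthy group, a two-scanner split, a gender
association with the scores, frontal NaN-dropout patches, and a low-SNR
spatially distributed score-linked signal embedded in the volumes.

All randomness flows through a single ``numpy.random.Generator`` so a cohort
is bit-reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupParams",
    "ScaleSpec",
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "DEFAULT_SCALE_SPECS",
    "SCALE_COLUMNS",
    "draw_scores",
    "generate_cohort",
    "generate_atlas",
    "write_cohort",
    "cohort_to_table",
]

#: CSV column name for each scale, in canonical order.
SCALE_COLUMNS = {
    "STAI-T": "stai_t",
    "STAI-S": "stai_s",
    "MASQ-D": "masq_d",
    "HAM-A": "ham_a",
    "HDRS": "hdrs",
}

GROUPS = ("distressed", "healthy")


@dataclass(frozen=True)
class GroupParams:
    """Target moments and bounds of one scale within one group."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError(
                f"bounds inverted or mean outside bounds: "
                f"min={self.minimum}, mean={self.mean}, max={self.maximum}"
            )
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class ScaleSpec:
    """Distributional specification of one clinical scale.

    ``zero_inflation_healthy`` is the probability that a healthy subject's
    score is exactly 0 (clinician-rated scales only); the continuous
    component is calibrated so that the *mixture* reproduces the target
    mean/sd of the healthy group.
    """

    name: str
    distressed: GroupParams
    healthy: GroupParams
    zero_inflation_healthy: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in SCALE_COLUMNS:
            raise ValueError(f"unknown scale name: {self.name!r}")
        if not 0.0 <= self.zero_inflation_healthy < 1.0:
            raise ValueError("zero_inflation_healthy must be in [0, 1)")
        if self.zero_inflation_healthy > 0 and self.name not in ("HAM-A", "HDRS"):
            raise ValueError("zero inflation is only meaningful for clinician scales")

    def group_params(self, group: str) -> GroupParams:
        if group not in GROUPS:
            raise ValueError(f"unknown group: {group!r}")
        return self.distressed if group == "distressed" else self.healthy


# Published per-group moments/ranges of the five scales.
DEFAULT_SCALE_SPECS: tuple[ScaleSpec, ...] = (
    ScaleSpec("STAI-T", GroupParams(54.9, 11.0, 25, 75), GroupParams(30.6, 5.7, 22, 47)),
    ScaleSpec("STAI-S", GroupParams(48.0, 10.8, 20, 75), GroupParams(28.7, 6.0, 20, 42)),
    ScaleSpec("MASQ-D", GroupParams(35.0, 12.0, 17, 59), GroupParams(15.3, 3.5, 12, 24)),
    ScaleSpec(
        "HAM-A",
        GroupParams(12.2, 6.3, 0, 27),
        GroupParams(0.6, 1.2, 0, 6),
        zero_inflation_healthy=47 / 72,
    ),
    ScaleSpec(
        "HDRS",
        GroupParams(15.0, 6.0, 2, 30),
        GroupParams(0.8, 1.5, 0, 7),
        zero_inflation_healthy=45 / 72,
    ),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``scanner_split`` maps each group to (scanner A count, scanner B count);
    the defaults mirror the study's 119/35 two-scanner composition with
    scanner B dominated by distressed subjects (which induces the
    scanner-score association the pipeline screens for).
    """

    n_distressed: int = 82
    n_healthy: int = 72
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    signal_snr: float = 0.2
    n_signal_voxels: int = 60
    scanner_split: dict = field(
        default_factory=lambda: {"distressed": (50, 32), "healthy": (69, 3)}
    )
    dropout_fraction: float = 0.0
    dropout_extent: float = 0.05
    seed: int = 0
    # --- secondary knobs (documented defaults) ---
    scale_correlation: float = 0.7
    gender_shift_sd: float = 0.25
    female_fraction: dict = field(
        default_factory=lambda: {"distressed": 56 / 82, "healthy": 47 / 72}
    )
    noise_sd: float = 1.0
    baseline: float = 0.0
    scanner_offset_sd: float = 0.5
    primary_scale: str = "STAI-T"
    signal_voxel_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_distressed < 1 or self.n_healthy < 1:
            raise ValueError("group sizes must be positive")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        n_vox = int(np.prod(self.grid_shape))
        if self.n_signal_voxels > n_vox:
            raise ValueError("n_signal_voxels exceeds number of voxels")
        if self.signal_snr < 0:
            raise ValueError("signal_snr must be nonnegative")
        if not (0.0 <= self.dropout_fraction <= 1.0 and 0.0 <= self.dropout_extent <= 1.0):
            raise ValueError("dropout fractions must lie in [0, 1]")
        for group, n in (("distressed", self.n_distressed), ("healthy", self.n_healthy)):
            split = self.scanner_split[group]
            if len(split) != 2 or min(split) < 0 or sum(split) != n:
                raise ValueError(
                    f"scanner_split for {group} must be two nonnegative counts "
                    f"summing to {n}, got {split}"
                )

    @property
    def n_total(self) -> int:
        return self.n_distressed + self.n_healthy


@dataclass
class SubjectRecord:
    subject_id: str
    volume: np.ndarray
    scores: dict
    age: float
    gender: str
    scanner: str
    group: str


@dataclass
class GroundTruth:
    """What was planted: the score-linked weight pattern and scanner offset."""

    true_weight_volume: np.ndarray
    signal_voxel_indices: np.ndarray
    scanner_offset_volume: np.ndarray


# ---------------------------------------------------------------------------
# truncated-normal calibration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _calibrate_truncnorm(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    target mean and sd.

    Truncation shifts moments, so drawing straight from N(target_mean,
    target_sd) and clipping would *not* reproduce the published numbers;
    we invert the truncated-moment map instead.
    """
    # truncation negligible: bounds many sds away from the mean
    if min(target_mean - lo, hi - target_mean) > 8 * target_sd:
        return target_mean, target_sd

    def residuals(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - target_mean, np.sqrt(v) - target_sd])

    sol = optimize.least_squares(
        residuals, x0=np.array([target_mean, np.log(target_sd)]), xtol=1e-12, ftol=1e-12
    )
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))

    # The target sd can sit (slightly) outside what the truncated-normal
    # family supports on [lo, hi] (heavily skewed clinician-scale targets);
    # keep the best-fit sigma but refine mu so the mean is matched exactly.
    def mean_residual(m: float) -> float:
        a, b = (lo - m) / sigma, (hi - m) / sigma
        return float(stats.truncnorm.mean(a, b, loc=m, scale=sigma) - target_mean)

    span = hi - lo + 10 * sigma
    try:
        mu = float(optimize.brentq(mean_residual, lo - span, hi + span, xtol=1e-12))
    except ValueError:
        pass  # keep least-squares mu; checked below
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    achieved_mean = float(stats.truncnorm.mean(a, b, loc=mu, scale=sigma))
    if abs(achieved_mean - target_mean) > 1e-6 * max(target_sd, 1.0):
        raise ValueError(
            f"truncated-normal calibration failed for mean={target_mean}, "
            f"sd={target_sd} on [{lo}, {hi}]"
        )
    return mu, sigma


def _component_targets(spec: ScaleSpec, group: str) -> tuple[float, float, float]:
    """(mean, sd, zero-inflation) of the continuous component for a group.

    For zero-inflated scales the published mean/sd describe the mixture
    ``0 w.p. p, continuous w.p. 1-p``; solve for the component moments.
    """
    params = spec.group_params(group)
    p0 = spec.zero_inflation_healthy if group == "healthy" else 0.0
    if p0 == 0.0:
        return params.mean, params.sd, 0.0
    q = 1.0 - p0
    comp_mean = params.mean / q
    comp_var = (params.sd**2 + params.mean**2) / q - comp_mean**2
    if comp_var <= 0:
        raise ValueError(
            f"infeasible zero-inflation for {spec.name}: component variance <= 0"
        )
    return comp_mean, float(np.sqrt(comp_var)), p0


def _scale_ppf(spec: ScaleSpec, group: str, u: np.ndarray) -> np.ndarray:
    """Quantile transform of uniform draws into scale values.

    The lowest ``p0`` quantile mass maps to exact zeros (clinician scales,
    healthy group); the remainder goes through the calibrated truncated
    normal. Monotone in ``u`` so copula correlations survive the transform.
    """
    params = spec.group_params(group)
    comp_mean, comp_sd, p0 = _component_targets(spec, group)
    mu, sigma = _calibrate_truncnorm(comp_mean, comp_sd, params.minimum, params.maximum)
    a, b = (params.minimum - mu) / sigma, (params.maximum - mu) / sigma
    out = np.zeros_like(u, dtype=float)
    nonzero = u >= p0
    u_comp = (u[nonzero] - p0) / (1.0 - p0)
    # clip away exact 0/1 to keep ppf finite
    u_comp = np.clip(u_comp, 1e-12, 1 - 1e-12)
    out[nonzero] = stats.truncnorm.ppf(u_comp, a, b, loc=mu, scale=sigma)
    return out


def draw_scores(
    spec: ScaleSpec, group: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent scores for one scale and group.

    Values come from a truncated normal calibrated so the *empirical*
    moments match the spec; for zero-inflated scales a point mass at 0
    replaces the draw with the configured probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _scale_ppf(spec, group, rng.random(n))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _correlated_uniforms(
    n: int, n_scales: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-copula uniforms with exchangeable correlation ``rho``."""
    corr = np.full((n_scales, n_scales), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, n_scales)) @ chol.T
    return stats.norm.cdf(z)


def _dropout_patch(
    grid_shape: tuple[int, int, int], n_nan: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel coordinates of a contiguous patch of exactly ``n_nan`` voxels.

    The patch is an axis-aligned box anchored at the grid corner of a fixed
    ("frontal") octant, trimmed in raster order to hit the exact count.
    """
    nx, ny, nz = grid_shape
    n_nan = min(n_nan, nx * ny * nz)
    # grow a near-cubic box from the corner until it covers n_nan voxels
    dims = np.array([1, 1, 1])
    while np.prod(dims) < n_nan:
        growable = [i for i in range(3) if dims[i] < grid_shape[i]]
        i = min(growable, key=lambda j: dims[j])
        dims[i] += 1
    box = np.stack(
        np.meshgrid(
            np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    box = box[:n_nan]
    return box[:, 0], box[:, 1], box[:, 2]


def generate_cohort(
    config: CohortConfig,
    scale_specs: tuple[ScaleSpec, ...] = DEFAULT_SCALE_SPECS,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Forward model per subject volume::

        baseline + z(primary score) * amplitude * true_weights
                 + scanner_offset (scanner B only) + N(0, noise_sd)

    with ``amplitude = signal_snr * noise_sd`` so the per-signal-voxel SD of
    the score-linked term equals ``signal_snr`` noise SDs. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    spec_by_name = {s.name: s for s in scale_specs}
    if config.primary_scale not in spec_by_name:
        raise ValueError(f"primary scale {config.primary_scale!r} not in scale specs")
    scale_names = [s.name for s in scale_specs]

    # --- scores, per group, copula-correlated across scales ---
    frames: dict[str, dict[str, np.ndarray]] = {}
    for group, n in (("distressed", config.n_distressed), ("healthy", config.n_healthy)):
        u = _correlated_uniforms(n, len(scale_specs), config.scale_correlation, rng)
        frames[group] = {
            name: _scale_ppf(spec_by_name[name], group, u[:, j])
            for j, name in enumerate(scale_names)
        }

    # --- demographics ---
    records: list[SubjectRecord] = []
    group_of: list[str] = ["distressed"] * config.n_distressed + [
        "healthy"
    ] * config.n_healthy
    genders: list[str] = []
    scanners: list[str] = []
    for group, n in (("distressed", config.n_distressed), ("healthy", config.n_healthy)):
        n_f = int(round(config.female_fraction[group] * n))
        g = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(g)
        genders.extend(g.tolist())
        n_a, n_b = config.scanner_split[group]
        sc = np.array(["A"] * n_a + ["B"] * n_b)
        rng.shuffle(sc)
        scanners.extend(sc.tolist())
    ages = np.clip(rng.normal(21.6, 2.0, config.n_total), 18.0, 25.0)

    # --- mean-preserving gender shift on the scores ---
    # females move up, males down, weighted so the group mean is unchanged.
    scores_by_subject: list[dict] = []
    offsets = {"distressed": 0, "healthy": config.n_distressed}
    for i in range(config.n_total):
        group = group_of[i]
        j = i - offsets[group]
        row = {}
        for name in scale_names:
            spec = spec_by_name[name]
            params = spec.group_params(group)
            val = frames[group][name][j]
            if config.gender_shift_sd > 0:
                f_frac = config.female_fraction[group]
                delta = config.gender_shift_sd * params.sd
                shift = (1 - f_frac) * delta if genders[i] == "F" else -f_frac * delta
                if not (spec.zero_inflation_healthy > 0 and val == 0.0):
                    val = float(np.clip(val + shift, params.minimum, params.maximum))
            row[name] = float(val)
        scores_by_subject.append(row)

    # --- ground-truth signal pattern ---
    n_vox = int(np.prod(config.grid_shape))
    if config.signal_voxel_indices is not None:
        sig_idx = np.asarray(config.signal_voxel_indices, dtype=int)
        if sig_idx.size != config.n_signal_voxels:
            raise ValueError("signal_voxel_indices length must equal n_signal_voxels")
    else:
        sig_idx = rng.choice(n_vox, size=config.n_signal_voxels, replace=False)
    true_w = np.zeros(n_vox)
    true_w[sig_idx] = 1.0
    true_weight_volume = true_w.reshape(config.grid_shape, order="F")
    scanner_offset_volume = rng.normal(
        0.0, config.scanner_offset_sd, config.grid_shape
    )

    primary = np.array([s[config.primary_scale] for s in scores_by_subject])
    z_primary = (primary - primary.mean()) / (primary.std() or 1.0)
    amplitude = config.signal_snr * config.noise_sd

    # --- dropout assignment ---
    n_drop = int(round(config.dropout_fraction * config.n_total))
    drop_subjects = set(
        rng.choice(config.n_total, size=n_drop, replace=False).tolist()
    )
    n_nan = int(round(config.dropout_extent * n_vox))
    patch = _dropout_patch(config.grid_shape, n_nan) if n_nan else None

    for i in range(config.n_total):
        vol = (
            config.baseline
            + z_primary[i] * amplitude * true_weight_volume
            + rng.normal(0.0, config.noise_sd, config.grid_shape)
        )
        if scanners[i] == "B":
            vol = vol + scanner_offset_volume
        if i in drop_subjects and patch is not None:
            vol[patch] = np.nan
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:04d}",
                volume=vol,
                scores=scores_by_subject[i],
                age=float(ages[i]),
                gender=genders[i],
                scanner=scanners[i],
                group=group_of[i],
            )
        )

    truth = GroundTruth(
        true_weight_volume=true_weight_volume,
        signal_voxel_indices=np.sort(sig_idx),
        scanner_offset_volume=scanner_offset_volume,
    )
    return records, truth


def cohort_to_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table with one row per subject, canonical column order."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "scanner": r.scanner,
            "gender": r.gender,
            "age": r.age,
        }
        row.update({SCALE_COLUMNS[name]: val for name, val in r.scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def _balanced_factorization(
    n_regions: int, grid_shape: tuple[int, int, int]
) -> tuple[int, int, int] | None:
    """Factor ``n_regions`` into per-axis split counts, near-cubic, each
    factor bounded by the axis length. None if no feasible factorization."""
    best = None
    for f0 in range(1, min(n_regions, grid_shape[0]) + 1):
        if n_regions % f0:
            continue
        rest = n_regions // f0
        for f1 in range(1, min(rest, grid_shape[1]) + 1):
            if rest % f1:
                continue
            f2 = rest // f1
            if f2 > grid_shape[2]:
                continue
            spread = max(f0, f1, f2) - min(f0, f1, f2)
            if best is None or spread < best[0]:
                best = (spread, (f0, f1, f2))
    return None if best is None else best[1]


def generate_atlas(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Partition the grid into ``n_regions`` contiguous labelled blocks.

    Labels run 1..n_regions. Splits each axis into near-equal slabs using a
    balanced factorization of ``n_regions`` (6x6x6 with 8 regions gives the
    octant labelling); falls back to contiguous raster-order runs when
    ``n_regions`` has no feasible 3-axis factorization.
    """
    n_vox = int(np.prod(grid_shape))
    if n_regions < 1 or n_regions > n_vox:
        raise ValueError(f"n_regions must be in 1..{n_vox}, got {n_regions}")
    factors = _balanced_factorization(n_regions, grid_shape)
    atlas = np.zeros(grid_shape, dtype=np.int32)
    if factors is not None:
        edges = [
            np.array_split(np.arange(grid_shape[ax]), factors[ax]) for ax in range(3)
        ]
        label = 1
        for ix in edges[0]:
            for iy in edges[1]:
                for iz in edges[2]:
                    atlas[np.ix_(ix, iy, iz)] = label
                    label += 1
    else:
        flat = np.zeros(n_vox, dtype=np.int32)
        for label, chunk in enumerate(np.array_split(np.arange(n_vox), n_regions), 1):
            flat[chunk] = label
        atlas = flat.reshape(grid_shape, order="F")
    return atlas


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def write_cohort(
    records: list[SubjectRecord],
    ground_truth: GroundTruth,
    out_dir: str | Path,
) -> dict:
    """Write one NIfTI per subject, the subject table, the ground truth and
    a JSON manifest; returns the manifest dict.

    Content hashes in the manifest are computed over in-memory array bytes
    (not compressed files), so identical cohorts yield identical manifests.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    files = []
    for r in records:
        fname = f"{r.subject_id}.nii.gz"
        nib.save(nib.Nifti1Image(r.volume.astype(np.float64), affine), out_dir / fname)
        files.append(
            {
                "subject_id": r.subject_id,
                "file": fname,
                "sha256": hashlib.sha256(
                    np.ascontiguousarray(r.volume.astype(np.float64)).tobytes()
                ).hexdigest(),
            }
        )
    table = cohort_to_table(records)
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    nib.save(
        nib.Nifti1Image(ground_truth.true_weight_volume.astype(np.float64), affine),
        out_dir / "truth.nii.gz",
    )
    manifest = {
        "n_subjects": len(records),
        "grid_shape": list(records[0].volume.shape) if records else [],
        "volumes": files,
        "table": "cohort.csv",
        "table_sha256": hashlib.sha256(csv_path.read_bytes()).hexdigest(),
        "truth": "truth.nii.gz",
        "truth_sha256": hashlib.sha256(
            np.ascontiguousarray(
                ground_truth.true_weight_volume.astype(np.float64)
            ).tobytes()
        ).hexdigest(),
        "signal_voxel_indices": ground_truth.signal_voxel_indices.tolist(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    if "grid_shape" in d:
        d["grid_shape"] = tuple(d["grid_shape"])
    if "scanner_split" in d:
        d["scanner_split"] = {k: tuple(v) for k, v in d["scanner_split"].items()}
    if "signal_voxel_indices" in d and d["signal_voxel_indices"] is not None:
        d["signal_voxel_indices"] = tuple(d["signal_voxel_indices"])
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**d)
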