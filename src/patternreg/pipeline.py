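"""End-to-end orchestration: simulate -> QC/mask -> decode -> permute ->
localize -> report, driven by a single YAML config.

Every stage records the config hash and the seeds it consumed, report JSON
floats are rounded to 12 significant digits, and a failure in one
scale x scheme cell marks that cell as failed without aborting the rest of
the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .confounds import screen_confounds
from .cv import CrossValidator, GPCSpec, GPRSpec, make_balanced_folds
from .gp import reconstruct_weights
from .localization import average_weight_maps, region_normalized_weights, top_k_summary
from .masking import (
    BrainMask,
    assemble_features,
    build_common_mask,
    default_scope_mask,
    exclude_subjects,
    exclusion_report,
    load_volume,
    save_mask,
)
from .metrics import (
    MetricResult,
    balanced_accuracy,
    bonferroni_threshold,
    normalized_mse,
    pearson_r,
    permutation_test,
)
from .synthetic import (
    SCALE_COLUMNS,
    config_from_dict,
    generate_atlas,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger("patternreg")

DEFAULT_CONFIG: dict = {
    "cohort": {},  # CohortConfig fields; defaults mirror the study layout
    "atlas": {"n_regions": 27},
    "paths": {"cohort_dir": "cohort", "atlas": "atlas.nii.gz", "out_dir": "run"},
    "decode": {
        "scales": ["stai_t", "stai_s", "masq_d", "ham_a", "hdrs"],
        "cv_schemes": [2, 5],
        "scopes": ["whole"],
        "n_permutations": 1000,
        "confounds": ["age"],
        "confounds_distressed": ["age", "scanner"],
        "balance_keys": ["scanner"],
        "alpha": 0.05,
        "nw_mode": "literal",
        "top_k": 20,
    },
    "seeds": {"cohort": 0, "folds": 1, "permutations": 2},
}


def load_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in config:
                raise ValueError(f"unknown config section: {section!r}")
            if isinstance(values, dict):
                config[section].update(values)
            else:
                config[section] = values
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _round_sig(x: float, digits: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _round_floats(obj):
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def simulate(config: dict, base_dir: str | Path = ".") -> dict:
    """Generate and write a synthetic cohort plus atlas; returns manifest."""
    base = Path(base_dir)
    cohort_cfg = dict(config["cohort"])
    cohort_cfg.setdefault("seed", config["seeds"]["cohort"])
    cc = config_from_dict(cohort_cfg)
    t0 = time.monotonic()
    records, truth = generate_cohort(cc)
    cohort_dir = base / config["paths"]["cohort_dir"]
    manifest = write_cohort(records, truth, cohort_dir)
    atlas = generate_atlas(cc.grid_shape, config["atlas"]["n_regions"])
    import nibabel as nib

    atlas_path = base / config["paths"]["atlas"]
    atlas_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(atlas.astype(np.int32), np.eye(4)), atlas_path)
    manifest["config_hash"] = config_hash(config)
    manifest["seed"] = cc.seed
    with open(cohort_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info(
        "simulate: %d subjects on %s grid in %.1fs",
        len(records), cc.grid_shape, time.monotonic() - t0,
    )
    return manifest


def load_cohort(cohort_dir: str | Path) -> tuple[list[np.ndarray], pd.DataFrame]:
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    volumes = [
        load_volume(cohort_dir / f"{sid}.nii.gz") for sid in table["subject_id"]
    ]
    return volumes, table


def prepare_features(
    volumes: list[np.ndarray], table: pd.DataFrame, out_dir: Path | None = None
):
    """Exclusion -> common mask -> feature matrix; optionally writes the
    exclusion report and mask."""
    scope = default_scope_mask(volumes)
    ids = table["subject_id"].tolist()
    kept, excluded = exclude_subjects(volumes, scope, subject_ids=ids)
    kept_set = set(kept)
    kept_idx = [i for i, sid in enumerate(ids) if sid in kept_set]
    kept_volumes = [volumes[i] for i in kept_idx]
    kept_table = table.iloc[kept_idx].reset_index(drop=True)
    mask = build_common_mask(kept_volumes, scope)
    features = assemble_features(kept_volumes, mask, subject_ids=kept)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        exclusion_report(volumes, scope, subject_ids=ids).to_csv(
            out_dir / "exclusions.csv", index=False
        )
        save_mask(mask, out_dir / "mask.nii.gz")
    logger.info(
        "masking: kept %d/%d subjects, %d common voxels",
        len(kept), len(ids), mask.voxel_count,
    )
    return features, kept_table, mask


def _scope_rows(table: pd.DataFrame, scope: str) -> np.ndarray:
    if scope == "whole":
        return np.arange(len(table))
    if scope in ("distressed", "healthy"):
        return np.flatnonzero((table["group"] == scope).to_numpy())
    raise ValueError(f"unknown scope: {scope!r}")


def decode(config: dict, base_dir: str | Path = ".") -> dict:
    """Run the full pattern-regression grid and write report.json."""
    base = Path(base_dir)
    out_dir = base / config["paths"]["out_dir"]
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes, table = load_cohort(base / config["paths"]["cohort_dir"])
    features, table, mask = prepare_features(volumes, table, out_dir)

    dc = config["decode"]
    scales = [SCALE_COLUMNS.get(s, s) for s in dc["scales"]]
    screenable = [s for s in scales if s in table.columns]
    if screenable:
        screen = screen_confounds(
            table, screenable,
            [c for c in ("scanner", "gender", "age") if c in table],
        )
        screen.to_csv(out_dir / "associations.csv", index=False)

    n_cells = len(scales) * len(dc["cv_schemes"])
    threshold = bonferroni_threshold(len(scales), len(dc["cv_schemes"]))
    report: dict = {
        "provenance": {
            "config_hash": config_hash(config),
            "seeds": config["seeds"],
            "version": __version__,
            "n_subjects": int(features.n_subjects),
            "n_voxels": int(features.n_voxels),
        },
        "bonferroni_threshold": threshold,
        "cells": [],
    }
    atlas_path = base / config["paths"]["atlas"]
    atlas = load_volume(atlas_path).astype(int) if atlas_path.exists() else None

    for scope in dc["scopes"]:
        rows = _scope_rows(table, scope)
        scope_table = table.iloc[rows].reset_index(drop=True)
        scope_features = features.values[rows]
        conf_names = (
            dc["confounds_distressed"] if scope == "distressed" else dc["confounds"]
        )
        conf_names = [c for c in conf_names if scope_table[c].nunique() > 1]
        for scale in scales:
            for k in dc["cv_schemes"]:
                cell = {"scope": scope, "scale": scale, "cv_k": int(k)}
                t0 = time.monotonic()
                try:
                    cell.update(
                        _decode_cell(
                            scope_features, scope_table, scale, k, conf_names,
                            dc, config["seeds"], atlas, mask, out_dir, scope,
                        )
                    )
                    cell["status"] = "ok"
                    cell["significant_r"] = cell["p_r"] < threshold
                    cell["significant_mse"] = cell["p_mse"] < threshold
                except Exception as exc:  # crash isolation per cell
                    logger.warning("cell %s failed: %s", cell, exc)
                    cell["status"] = "failed"
                    cell["error"] = str(exc)
                # timings go to the log, not the report (byte determinism)
                logger.info("cell %s/%s/k=%s: %.1fs", scope, scale, k,
                            time.monotonic() - t0)
                report["cells"].append(cell)
    write_json(report, out_dir / "report.json")
    return report


def _decode_cell(
    features_values, scope_table, scale, k, conf_names, dc, seeds, atlas, mask,
    out_dir, scope,
) -> dict:
    targets = scope_table[scale].to_numpy(dtype=float)
    folds = make_balanced_folds(
        scope_table, k, scale,
        balance_keys=tuple(dc["balance_keys"]),
        alpha=dc["alpha"],
        rng=np.random.default_rng(seeds["folds"]),
    )
    cv = CrossValidator(features_values, scope_table, conf_names, folds, GPRSpec())

    def closure(y: np.ndarray) -> MetricResult:
        result = cv.run(y)
        return MetricResult(
            pearson_r=pearson_r(result.predicted, result.actual),
            normalized_mse=normalized_mse(result.predicted, result.actual),
            n=len(y),
        )

    perm = permutation_test(
        closure, targets, n_permutations=dc["n_permutations"],
        seed=seeds["permutations"],
    )
    result = cv.run(targets, return_models=True)

    # per-fold dual-to-primal weights -> averaged unit-norm map
    fold_weights = [
        reconstruct_weights(model, state["X_train"])
        for _, model, state in result.models
    ]
    weight_map = average_weight_maps(fold_weights)
    import nibabel as nib

    tag = f"{scope}_{scale}_k{k}"
    nib.save(
        nib.Nifti1Image(weight_map.to_volume(mask), np.eye(4)),
        out_dir / f"weights_{tag}.nii.gz",
    )
    folds.to_frame(scope_table["subject_id"]).to_csv(
        out_dir / f"folds_{tag}.csv", index=False
    )
    pd.DataFrame(
        {
            "subject_id": scope_table["subject_id"],
            "group": scope_table["group"],
            "actual": result.actual,
            "predicted": result.predicted,
            "fold": result.fold,
        }
    ).to_csv(out_dir / f"scatter_{tag}.csv", index=False)

    cell = {
        "r": perm.observed.pearson_r,
        "nmse": perm.observed.normalized_mse,
        "p_r": perm.p_r,
        "p_mse": perm.p_mse,
        "p_r_conservative": perm.p_r_conservative,
        "p_mse_conservative": perm.p_mse_conservative,
        "n_perm": perm.n_permutations,
        "seed": perm.seed,
        "fold_sizes": folds.sizes.tolist(),
        "confounds": list(conf_names),
        "weight_map": f"weights_{tag}.nii.gz",
    }
    if atlas is not None:
        regions = region_normalized_weights(
            weight_map, atlas, mask, mode=dc["nw_mode"]
        )
        regions.to_csv(out_dir / f"regions_{tag}.csv", index=False)
        top, cum = top_k_summary(regions, min(dc["top_k"], len(regions)))
        cell["top_regions"] = top["region"].tolist()
        cell["top_pct_nw_sum"] = cum
    return cell


def classify(config: dict, base_dir: str | Path = ".") -> dict:
    """Distressed-vs-healthy GPC with the same folds machinery."""
    base = Path(base_dir)
    out_dir = base / config["paths"]["out_dir"]
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes, table = load_cohort(base / config["paths"]["cohort_dir"])
    features, table, mask = prepare_features(volumes, table)
    dc = config["decode"]
    if table["group"].nunique() < 2:
        raise ValueError("classification needs both groups present")
    labels = (table["group"] == "distressed").to_numpy(dtype=int)
    report: dict = {
        "provenance": {
            "config_hash": config_hash(config),
            "seeds": config["seeds"],
            "version": __version__,
        },
        "cells": [],
    }
    rng = np.random.default_rng(config["seeds"]["permutations"])
    for k in dc["cv_schemes"]:
        folds = make_balanced_folds(
            table, k, "stai_t",
            balance_keys=tuple(dc["balance_keys"]),
            alpha=dc["alpha"],
            rng=np.random.default_rng(config["seeds"]["folds"]),
        )
        conf_names = [c for c in dc["confounds"] if table[c].nunique() > 1]
        cv = CrossValidator(features.values, table, conf_names, folds, GPCSpec())
        result = cv.run(labels)
        bal, per_class = balanced_accuracy(labels, result.predicted.astype(int))
        null = np.empty(dc["n_permutations"])
        for i in range(dc["n_permutations"]):
            perm = cv.run(rng.permutation(labels))
            null[i] = balanced_accuracy(perm.actual.astype(int),
                                        perm.predicted.astype(int))[0]
        p = float(np.mean(null >= bal))
        report["cells"].append(
            {
                "cv_k": int(k),
                "balanced_accuracy": bal,
                "accuracy_distressed": per_class[1],
                "accuracy_healthy": per_class[0],
                "p_value": p,
                "p_value_conservative": (float(np.sum(null >= bal)) + 1)
                / (dc["n_permutations"] + 1),
                "n_perm": int(dc["n_permutations"]),
            }
        )
    write_json(report, out_dir / "classification.json")
    return report


def localize(
    config: dict, weight_map_path: str | Path, base_dir: str | Path = "."
) -> pd.DataFrame:
    """Region table for an already-written weight-map NIfTI."""
    base = Path(base_dir)
    out_dir = base / config["paths"]["out_dir"]
    atlas = load_volume(base / config["paths"]["atlas"]).astype(int)
    mask_vol = load_volume(out_dir / "mask.nii.gz")
    mask = BrainMask(mask_vol > 0)
    weights_vol = load_volume(weight_map_path)
    weights = weights_vol.ravel(order="F")[mask.flat_indices]
    from .localization import WeightMap

    wm = WeightMap(weights=weights / np.linalg.norm(weights), n_folds=0)
    regions = region_normalized_weights(
        wm, atlas, mask, mode=config["decode"]["nw_mode"]
    )
    out = out_dir / (Path(weight_map_path).stem.split(".")[0] + "_regions.csv")
    regions.to_csv(out, index=False)
    return regions


def summarize(config: dict, base_dir: str | Path = ".") -> str:
    """Human-readable Table-2-style metrics grid plus provenance."""
    out_dir = Path(base_dir) / config["paths"]["out_dir"]
    with open(out_dir / "report.json") as fh:
        report = json.load(fh)
    rows = []
    for cell in report["cells"]:
        if cell.get("status") == "ok":
            rows.append(
                {
                    "scope": cell["scope"],
                    "scale": cell["scale"],
                    "cv_k": cell["cv_k"],
                    "r": cell["r"],
                    "p_r": cell["p_r"],
                    "nmse": cell["nmse"],
                    "p_mse": cell["p_mse"],
                    "significant_r": cell["significant_r"],
                }
            )
        else:
            rows.append(
                {
                    "scope": cell["scope"],
                    "scale": cell["scale"],
                    "cv_k": cell["cv_k"],
                    "r": float("nan"),
                    "p_r": float("nan"),
                    "nmse": float("nan"),
                    "p_mse": float("nan"),
                    "significant_r": False,
                }
            )
    grid = pd.DataFrame(rows)
    grid.to_csv(out_dir / "metrics.csv", index=False)
    lines = [
        "Metrics grid (one row per scale x CV scheme):",
        grid.to_string(index=False),
        "",
        f"Bonferroni threshold: {report['bonferroni_threshold']}",
        f"Config hash: {report['provenance']['config_hash']}",
        f"Seeds: {report['provenance']['seeds']}",
    ]
    return "\n".join(lines)
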