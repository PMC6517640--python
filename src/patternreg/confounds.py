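"""Confound screening and train/test-separated confound removal.

Associations between confounds and the to-be-predicted scores are screened
with two-sample t-tests (binary confounds) and Pearson correlations
(continuous confounds), without multiplicity correction — screening only.

Confound effects are removed from the *features*, never from the targets:
residualizing variables associated with the prediction target would strip
target-related variability. The regression coefficients are estimated on
training rows only and then applied unchanged to test rows, so no test-fold
information leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfoundModel",
    "screen_confounds",
    "fit_confound_model",
    "remove_confounds",
]


@dataclass(frozen=True)
class ConfoundModel:
    """Training-fold confound regression state.

    Carries only training-derived quantities (dummy encodings, z-scoring
    statistics, least-squares coefficients); applying it to test rows cannot
    touch test targets by construction.
    """

    names: tuple
    coefficients: np.ndarray  # (q+1) x n_voxels, row 0 = intercept
    level_maps: dict  # categorical confound -> level coded as 1
    standardize: dict  # continuous confound -> (train mean, train sd)

    @property
    def n_confounds(self) -> int:
        return len(self.names)


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(
        series.dtype, pd.CategoricalDtype
    ) or series.dtype == bool


def screen_confounds(
    table: pd.DataFrame, scales: list[str], confounds: list[str]
) -> pd.DataFrame:
    """Confound-score association screen.

    One row per (confound, scale): Welch two-sample t-test for binary
    confounds, Pearson correlation test for continuous ones.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects to screen confounds")
    rows = []
    for conf in confounds:
        col = table[conf]
        for scale in scales:
            y = table[scale].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                raise ValueError(f"scale {scale!r} is constant")
            if _is_categorical(col):
                levels = sorted(col.unique())
                if len(levels) != 2:
                    raise ValueError(
                        f"confound {conf!r} must have exactly 2 levels, "
                        f"got {levels}"
                    )
                a = y[(col == levels[0]).to_numpy()]
                b = y[(col == levels[1]).to_numpy()]
                stat, p = stats.ttest_ind(a, b, equal_var=False)
                test = "two-sample t"
            else:
                x = col.to_numpy(dtype=float)
                if np.ptp(x) == 0:
                    raise ValueError(f"confound {conf!r} is constant")
                stat, p = stats.pearsonr(x, y)
                test = "pearson"
            rows.append(
                {
                    "confound": conf,
                    "scale": scale,
                    "test": test,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def _encode_design(
    table: pd.DataFrame,
    names: tuple,
    level_maps: dict,
    standardize: dict,
) -> np.ndarray:
    """[1, confounds...] design using stored (training) encodings."""
    n = len(table)
    cols = [np.ones(n)]
    for name in names:
        col = table[name]
        if name in level_maps:
            cols.append((col == level_maps[name]).to_numpy(dtype=float))
        else:
            mean, sd = standardize[name]
            cols.append((col.to_numpy(dtype=float) - mean) / sd)
    return np.column_stack(cols)


def fit_confound_model(
    train_features: np.ndarray, train_confounds: pd.DataFrame, names: list[str]
) -> ConfoundModel:
    """Least-squares regression of every feature column on the confounds,
    training rows only.

    Categorical confounds become a 0/1 dummy for their second sorted level;
    continuous confounds are z-scored with training-fold statistics.
    """
    names = tuple(names)
    X = np.asarray(train_features, dtype=float)
    n = X.shape[0]
    if n <= len(names) + 1:
        raise ValueError("need n_train > number of confounds + 1")
    level_maps: dict = {}
    standardize: dict = {}
    for name in names:
        col = train_confounds[name]
        if _is_categorical(col):
            levels = sorted(col.unique())
            if len(levels) > 2:
                raise ValueError(f"confound {name!r} must be binary")
            level_maps[name] = levels[-1]
        else:
            vals = col.to_numpy(dtype=float)
            sd = float(vals.std(ddof=0))
            if sd == 0:
                raise ValueError(f"confound {name!r} is constant on training rows")
            standardize[name] = (float(vals.mean()), sd)
    design = _encode_design(train_confounds, names, level_maps, standardize)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confound design is rank deficient")
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    return ConfoundModel(
        names=names,
        coefficients=coef,
        level_maps=level_maps,
        standardize=standardize,
    )


def remove_confounds(
    model: ConfoundModel, features: np.ndarray, confounds: pd.DataFrame
) -> np.ndarray:
    """Subtract the training-estimated confound fit from ``features``."""
    for name in model.names:
        if name not in confounds.columns:
            raise ValueError(f"confound column {name!r} missing")
    design = _encode_design(confounds, model.names, model.level_maps, model.standardize)
    return np.asarray(features, dtype=float) - design @ model.coefficients
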