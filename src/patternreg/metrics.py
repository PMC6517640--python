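"""Agreement metrics, permutation inference and multiplicity control.

The normalized MSE follows the asymmetric definition used for the decoding
results: mean squared prediction error divided by the *range of the
predicted scores* (max minus min). Permutation p-values use the literal
count/n convention (which can reach exactly 0) alongside the conservative
(count+1)/(n+1) value; both are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "MetricResult",
    "PermutationResult",
    "pearson_r",
    "normalized_mse",
    "balanced_accuracy",
    "permutation_test",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class MetricResult:
    pearson_r: float
    normalized_mse: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"pearson_r out of [-1, 1]: {self.pearson_r}")
        if self.normalized_mse < 0:
            raise ValueError("normalized_mse must be nonnegative")
        if self.n < 3:
            raise ValueError("need n >= 3")


@dataclass(frozen=True)
class PermutationResult:
    observed: MetricResult
    null_r: tuple = field(repr=False, default=())
    null_mse: tuple = field(repr=False, default=())
    p_r: float = 1.0
    p_mse: float = 1.0
    p_r_conservative: float = 1.0
    p_mse_conservative: float = 1.0
    n_permutations: int = 0
    seed: int = 0


def pearson_r(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Sample Pearson correlation between predictions and actual scores."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.size != actual.size:
        raise ValueError("length mismatch")
    if predicted.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(predicted) == 0 or np.ptp(actual) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(predicted, actual).statistic)


def normalized_mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error divided by the range of the *predicted* scores."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.size != actual.size:
        raise ValueError("length mismatch")
    rng = float(np.ptp(predicted))
    if rng == 0:
        raise ValueError("constant predictions: normalized MSE undefined")
    return float(np.mean((predicted - actual) ** 2) / rng)


def balanced_accuracy(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> tuple[float, dict]:
    """Mean of per-class accuracies plus the per-class breakdown."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size != predicted_labels.size:
        raise ValueError("length mismatch")
    classes = np.unique(true_labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in true labels, got {classes}")
    per_class = {}
    for c in classes:
        in_class = true_labels == c
        per_class[c.item() if hasattr(c, "item") else c] = float(
            np.mean(predicted_labels[in_class] == c)
        )
    return float(np.mean(list(per_class.values()))), per_class


def permutation_test(
    pipeline: Callable[[np.ndarray], MetricResult],
    targets: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation inference on cross-validated prediction performance.

    ``pipeline`` must map a target vector through the *full* cross-validated
    procedure (confound removal refit per fold, model refit, prediction
    concatenation) to a :class:`MetricResult`; fold assignments stay fixed
    and only the targets are shuffled.

    ``p_r`` counts permutations whose \\|r\\| meets or exceeds the observed
    \\|r\\|; ``p_mse`` counts permutations whose MSE is at or *below* the
    observed one. Both are divided by ``n_permutations`` (so 0 is possible);
    the (count+1)/(n+1) variants are reported alongside.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    targets = np.asarray(targets, dtype=float)
    observed = pipeline(targets)
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_permutations)
    null_mse = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = pipeline(rng.permutation(targets))
        null_r[i] = perm.pearson_r
        null_mse[i] = perm.normalized_mse
    count_r = int(np.sum(np.abs(null_r) >= abs(observed.pearson_r)))
    count_mse = int(np.sum(null_mse <= observed.normalized_mse))
    return PermutationResult(
        observed=observed,
        null_r=tuple(null_r),
        null_mse=tuple(null_mse),
        p_r=count_r / n_permutations,
        p_mse=count_mse / n_permutations,
        p_r_conservative=(count_r + 1) / (n_permutations + 1),
        p_mse_conservative=(count_mse + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


def bonferroni_threshold(
    n_scales: int, n_cv_schemes: int, alpha: float = 0.05
) -> float:
    """Family-wise threshold ``alpha / (n_scales * n_cv_schemes)``."""
    if n_scales < 1 or n_cv_schemes < 1:
        raise ValueError("counts must be positive")
    return alpha / (n_scales * n_cv_schemes)
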