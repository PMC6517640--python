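"""Scanner-balanced cross-validation folds and the fit/predict loop.

Fold construction mechanizes the study's "manual" balancing: subjects are
dealt to folds greedily within each balance-key stratum (so every scanner
level is spread as evenly as integer divisibility allows and overall fold
sizes differ by at most one), and a candidate assignment is accepted only if
all pairwise two-sample t-tests on the target scale across folds have
p > alpha. Seeded rejection sampling retries until acceptance.

:class:`CrossValidator` precomputes everything that does not depend on the
target vector (confound residualization, per-fold kernels and their
eigendecompositions), so a permutation test that re-runs the CV with
shuffled targets costs O(n^2) per permutation instead of O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .confounds import fit_confound_model, remove_confounds
from .gp import (
    _EigenEvidence,
    fit_gpc,
    fit_gpr,
    linear_kernel,
    predict_gpc,
    predict_gpr,
)

__all__ = [
    "FoldAssignment",
    "PredictionResult",
    "BalanceError",
    "make_balanced_folds",
    "CrossValidator",
    "run_cv",
    "GPRSpec",
    "GPCSpec",
    "TrainMeanSpec",
]


class BalanceError(RuntimeError):
    """Raised when no acceptable fold assignment can be constructed."""


@dataclass(frozen=True)
class FoldAssignment:
    """Per-subject fold index (1..k) plus the balance diagnostics."""

    fold: np.ndarray
    k: int
    balance: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        fold = np.asarray(self.fold, dtype=int)
        object.__setattr__(self, "fold", fold)
        sizes = np.bincount(fold, minlength=self.k + 1)[1:]
        if (sizes == 0).any():
            raise ValueError("every fold must be nonempty")
        if fold.min() < 1 or fold.max() > self.k:
            raise ValueError("fold indices must lie in 1..k")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.fold, minlength=self.k + 1)[1:]

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)

    def to_frame(self, subject_ids) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": list(subject_ids), "fold": self.fold})


@dataclass(frozen=True)
class PredictionResult:
    """Fold-concatenated predictions in original subject order."""

    predicted: np.ndarray
    actual: np.ndarray
    fold: np.ndarray
    models: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        n = len(self.predicted)
        if not (len(self.actual) == len(self.fold) == n):
            raise ValueError("field lengths differ")


def _pairwise_target_pvalues(
    targets: np.ndarray, fold: np.ndarray, k: int
) -> list[float]:
    pvals = []
    for f1, f2 in combinations(range(1, k + 1), 2):
        a = targets[fold == f1]
        b = targets[fold == f2]
        if a.size < 2 or b.size < 2:
            continue  # singleton folds: t-test undefined, skipped
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals.append(1.0)
            continue
        pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
    return pvals


def make_balanced_folds(
    table: pd.DataFrame,
    k: int,
    target: str,
    balance_keys: tuple = ("scanner",),
    alpha: float = 0.05,
    max_tries: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> FoldAssignment:
    """Seeded rejection sampling for a balanced, distribution-checked split.

    Within every level combination of ``balance_keys`` subjects are dealt to
    the currently smallest folds (stratum count first, overall count second,
    random tie-break), then the assignment is accepted iff all pairwise
    t-tests on ``target`` across folds exceed ``alpha``.
    """
    n = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need n >= k")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    targets = table[target].to_numpy(dtype=float)

    if balance_keys:
        strata = table.groupby(list(balance_keys), sort=True).indices
        for level, idx in strata.items():
            if len(idx) < k:
                raise BalanceError(
                    f"balance level {level!r} has {len(idx)} subjects, "
                    f"fewer than k={k}: balancing infeasible"
                )
    else:
        strata = {"all": np.arange(n)}

    for _ in range(max_tries):
        fold = np.zeros(n, dtype=int)
        total = np.zeros(k, dtype=int)
        for _, idx in sorted(strata.items(), key=lambda kv: str(kv[0])):
            idx = np.asarray(idx)
            members = idx[rng.permutation(len(idx))]
            in_stratum = np.zeros(k, dtype=int)
            for subject in members:
                keys = in_stratum * (n + 1) * k + total * k + rng.integers(k, size=k)
                f = int(np.argmin(keys))
                fold[subject] = f + 1
                in_stratum[f] += 1
                total[f] += 1
        if total.max() - total.min() > 1:
            continue
        pvals = _pairwise_target_pvalues(targets, fold, k)
        if pvals and min(pvals) <= alpha:
            continue
        balance = {
            "fold_sizes": total.tolist(),
            "target_pvalues": pvals,
            "key_proportions": {
                str(level): np.bincount(fold[np.asarray(idx)], minlength=k + 1)[
                    1:
                ].tolist()
                for level, idx in strata.items()
            },
        }
        assignment = FoldAssignment(fold=fold, k=k, balance=balance)
        _assert_partition(assignment, n)
        return assignment
    raise BalanceError(f"no acceptable fold assignment in {max_tries} tries")


def _assert_partition(folds: FoldAssignment, n: int) -> None:
    """Union of test folds is the subject set; folds are disjoint."""
    seen = np.concatenate([folds.test_indices(f) for f in range(1, folds.k + 1)])
    if sorted(seen.tolist()) != list(range(n)):
        raise AssertionError("fold assignment is not a partition of the subjects")


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------


class GPRSpec:
    """Gaussian-process regression over a linear kernel.

    ``center`` subtracts training-fold voxel means from both sides before
    the kernel is formed (kernel centering). With an uncentered kernel the
    constant direction generally lies outside the kernel span, so the fixed
    training-mean offset leaks into the noise estimate and inflates sigma2;
    centering restores evidence-based noise recovery.
    """

    def __init__(self, center: bool = True):
        self.center = center

    def prepare(self, X_train: np.ndarray, X_test: np.ndarray) -> dict:
        X_train = np.asarray(X_train, dtype=float)
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        if self.center:
            col_means = X_train.mean(axis=0)
            X_train = X_train - col_means
            X_test = X_test - col_means
        K = linear_kernel(X_train, X_train)
        return {
            "K": K,
            "eigen": _EigenEvidence(K),
            "K_test_train": linear_kernel(X_test, X_train),
            "X_train": X_train,
        }

    def fit_predict(self, state: dict, y_train: np.ndarray):
        model = fit_gpr(state["K"], y_train, eigen=state["eigen"])
        return predict_gpr(model, state["K_test_train"]), model


class GPCSpec:
    """Probit-Laplace GP classification; predictions are class labels."""

    def __init__(self, center: bool = True):
        self.center = center

    def prepare(self, X_train: np.ndarray, X_test: np.ndarray) -> dict:
        X_train = np.asarray(X_train, dtype=float)
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        if self.center:
            col_means = X_train.mean(axis=0)
            X_train = X_train - col_means
            X_test = X_test - col_means
        return {
            "K": linear_kernel(X_train, X_train),
            "K_test_train": linear_kernel(X_test, X_train),
            "k_test_diag": np.sum(np.asarray(X_test, dtype=float) ** 2, axis=1),
            "X_train": X_train,
        }

    def fit_predict(self, state: dict, y_train: np.ndarray):
        classes = np.unique(y_train)
        if classes.size == 1:
            # degenerate fold (possible under label permutation at small n):
            # the only consistent classifier predicts the sole training class
            n_test = state["K_test_train"].shape[0]
            return np.full(n_test, classes[0]), None
        model = fit_gpc(state["K"], y_train)
        prob = predict_gpc(model, state["K_test_train"], state["k_test_diag"])
        labels = np.where(prob > 0.5, model.classes[1], model.classes[0])
        return labels, model


class TrainMeanSpec:
    """Stub: predict the training-target mean everywhere (test oracle)."""

    def prepare(self, X_train: np.ndarray, X_test: np.ndarray) -> dict:
        return {"n_test": np.atleast_2d(X_test).shape[0], "X_train": X_train}

    def fit_predict(self, state: dict, y_train: np.ndarray):
        return np.full(state["n_test"], np.asarray(y_train, float).mean()), None


class CrossValidator:
    """Target-independent CV state, re-runnable with new target vectors.

    Confound models are fit per training fold and applied to both sides
    *before* kernels are formed; none of that depends on the targets, so
    ``run`` can be called thousands of times (permutation null) at the cost
    of the model fits alone.
    """

    def __init__(
        self,
        features: np.ndarray,
        confounds: pd.DataFrame | None,
        confound_names: list[str],
        folds: FoldAssignment,
        model_spec,
    ):
        features = np.asarray(features, dtype=float)
        n = features.shape[0]
        if len(folds.fold) != n:
            raise ValueError("fold assignment length does not match features")
        if confounds is not None and len(confounds) != n:
            raise ValueError("confound table length does not match features")
        self.folds = folds
        self.model_spec = model_spec
        self.n = n
        self._fold_states = []
        for f in range(1, folds.k + 1):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            X_tr, X_te = features[tr], features[te]
            if confound_names:
                conf_tr = confounds.iloc[tr]
                conf_te = confounds.iloc[te]
                cmodel = fit_confound_model(X_tr, conf_tr, confound_names)
                X_tr = remove_confounds(cmodel, X_tr, conf_tr)
                X_te = remove_confounds(cmodel, X_te, conf_te)
            try:
                state = model_spec.prepare(X_tr, X_te)
            except Exception as exc:
                raise RuntimeError(f"fold {f}: preparation failed") from exc
            self._fold_states.append((f, tr, te, state))

    def run(self, targets: np.ndarray, return_models: bool = False) -> PredictionResult:
        targets = np.asarray(targets)
        if targets.shape[0] != self.n:
            raise ValueError("target length does not match features")
        predicted = np.empty(self.n, dtype=float)
        models = []
        for f, tr, te, state in self._fold_states:
            try:
                preds, model = self.model_spec.fit_predict(state, targets[tr])
            except Exception as exc:
                raise RuntimeError(f"fold {f}: model fitting failed") from exc
            predicted[te] = preds
            if return_models:
                models.append((f, model, state))
        return PredictionResult(
            predicted=predicted,
            actual=np.asarray(targets, dtype=float),
            fold=self.folds.fold.copy(),
            models=tuple(models),
        )


def run_cv(
    features: np.ndarray,
    targets: np.ndarray,
    confounds: pd.DataFrame | None,
    folds: FoldAssignment,
    model_spec,
    confound_names: list[str] = (),
    return_models: bool = False,
) -> PredictionResult:
    """One-shot CV: fit per fold on training rows, predict the held-out fold,
    concatenate predictions in original subject order."""
    cv = CrossValidator(features, confounds, list(confound_names), folds, model_spec)
    return cv.run(targets, return_models=return_models)
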