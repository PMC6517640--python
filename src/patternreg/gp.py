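"""Gaussian-process regression and classification with a linear kernel.

GPR: constant mean fixed at the training-target mean; covariance
``theta * K_lin + sigma2 * I``. Hyperparameters maximize the log marginal
likelihood over a log-spaced grid followed by Nelder-Mead refinement —
deterministic, no random restarts. Fitting reuses a single symmetric
eigendecomposition of the training kernel, so evaluating the evidence at a
new (theta, sigma2) costs O(n) and permutation loops that refit the model
thousands of times stay cheap.

Because the kernel is linear, the predictive mean is a linear function of
the features and the dual coefficients map back to a primal voxel-weight
vector ``w = theta * X_train.T @ alpha`` (dual/primal equivalence).

GPC: binary probit-likelihood GP via the Laplace approximation
(Rasmussen & Williams, Algorithms 3.1/3.2), labels coded -1/+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = [
    "GPRModel",
    "GPCModel",
    "linear_kernel",
    "log_marginal_likelihood",
    "fit_gpr",
    "predict_gpr",
    "reconstruct_weights",
    "fit_gpc",
    "predict_gpc",
]

GRID_SIZE = 20
GRID_SPAN = (1e-4, 1e4)
JITTER_REL = 1e-8


def linear_kernel(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Gram matrix of dot products between rows of ``Xa`` and ``Xb``."""
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    return Xa @ Xb.T


def _jitter(K: np.ndarray) -> float:
    return JITTER_REL * np.trace(K) / max(K.shape[0], 1)


def log_marginal_likelihood(
    K: np.ndarray, y: np.ndarray, theta: float, sigma2: float, mu: float = 0.0
) -> float:
    """Log evidence of ``y ~ N(mu, theta*K + sigma2*I)`` via Cholesky."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("K must be n x n matching y")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    C = theta * K + (sigma2 + _jitter(K)) * np.eye(n)
    try:
        factor = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite after jitter"
        ) from exc
    r = y - mu
    alpha = cho_solve(factor, r)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return float(-0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))


@dataclass
class GPRModel:
    """Fitted GPR state; ``alpha`` solves (theta*K + sigma2*I) alpha = y - mu."""

    theta: float
    sigma2: float
    mu: float
    alpha: np.ndarray
    train_index: np.ndarray | None = None
    kernel: str = "linear"
    log_evidence: float = float("-inf")

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "sigma2": self.sigma2,
            "mu": self.mu,
            "alpha": np.asarray(self.alpha).tolist(),
            "train_index": (
                None if self.train_index is None else np.asarray(self.train_index).tolist()
            ),
            "kernel": self.kernel,
            "log_evidence": self.log_evidence,
        }


class _EigenEvidence:
    """O(n) evidence evaluation after one eigendecomposition of K."""

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        self.n = K.shape[0]
        self.jitter = _jitter(K)
        evals, evecs = np.linalg.eigh(K)
        self.evals = np.clip(evals, 0.0, None)
        self.evecs = evecs

    def lml(self, r_rot: np.ndarray, theta: float, sigma2: float) -> float:
        d = theta * self.evals + sigma2 + self.jitter
        return float(
            -0.5 * np.sum(r_rot**2 / d)
            - 0.5 * np.sum(np.log(d))
            - 0.5 * self.n * np.log(2 * np.pi)
        )

    def solve(self, r: np.ndarray, theta: float, sigma2: float) -> np.ndarray:
        d = theta * self.evals + sigma2 + self.jitter
        return self.evecs @ ((self.evecs.T @ r) / d)


def fit_gpr(
    K: np.ndarray,
    y: np.ndarray,
    train_index: np.ndarray | None = None,
    eigen: _EigenEvidence | None = None,
) -> GPRModel:
    """Fit GPR hyperparameters by evidence maximization.

    ``eigen`` may carry a precomputed eigendecomposition of ``K`` so repeated
    fits on the same kernel (permutation tests) skip the O(n^3) step.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 training samples")
    mu = float(y.mean())
    r = y - mu
    var_y = float(r.var())
    if eigen is None:
        eigen = _EigenEvidence(K)

    if var_y == 0.0:
        # degenerate target: any hyperparameters give alpha = 0
        return GPRModel(
            theta=1e-12, sigma2=1e-12 + eigen.jitter, mu=mu,
            alpha=np.zeros(n), train_index=train_index, log_evidence=0.0,
        )

    # grid anchored at var(y); theta additionally rescaled by the kernel's
    # mean diagonal so theta*K and sigma2*I start on comparable scales
    k_scale = max(float(np.mean(np.diag(K))), 1e-300)
    theta_grid = np.logspace(
        np.log10(GRID_SPAN[0]), np.log10(GRID_SPAN[1]), GRID_SIZE
    ) * var_y / k_scale
    sigma2_grid = np.logspace(
        np.log10(GRID_SPAN[0]), np.log10(GRID_SPAN[1]), GRID_SIZE
    ) * var_y

    r_rot = eigen.evecs.T @ r
    # vectorized grid evaluation: d has shape (grid, grid, n)
    d = (
        theta_grid[:, None, None] * eigen.evals[None, None, :]
        + sigma2_grid[None, :, None]
        + eigen.jitter
    )
    lml_grid = -0.5 * np.sum(r_rot**2 / d, axis=-1) - 0.5 * np.sum(
        np.log(d), axis=-1
    ) - 0.5 * n * np.log(2 * np.pi)
    i, j = np.unravel_index(np.argmax(lml_grid), lml_grid.shape)
    best = (float(lml_grid[i, j]), float(theta_grid[i]), float(sigma2_grid[j]))

    def neg_lml(logp: np.ndarray) -> float:
        return -eigen.lml(r_rot, np.exp(logp[0]), np.exp(logp[1]))

    res = optimize.minimize(
        neg_lml,
        x0=np.log([best[1], best[2]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200},
    )
    if res.fun <= -best[0]:
        theta, sigma2 = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
        log_ev = float(-res.fun)
    else:  # refinement never worsens the grid optimum
        theta, sigma2, log_ev = best[1], best[2], best[0]
    alpha = eigen.solve(r, theta, sigma2)
    return GPRModel(
        theta=theta, sigma2=sigma2, mu=mu, alpha=alpha,
        train_index=train_index, log_evidence=log_ev,
    )


def predict_gpr(model: GPRModel, K_test_train: np.ndarray) -> np.ndarray:
    """Predictive mean ``mu + theta * K_test_train @ alpha``."""
    K_test_train = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K_test_train.shape[1] != model.alpha.size:
        raise ValueError(
            f"kernel columns ({K_test_train.shape[1]}) do not match "
            f"training size ({model.alpha.size})"
        )
    return model.mu + model.theta * K_test_train @ model.alpha


def reconstruct_weights(model: GPRModel, X_train: np.ndarray) -> np.ndarray:
    """Primal voxel weights ``w = theta * X_train.T @ alpha``.

    Satisfies ``predict(x*) = mu + x* @ w`` exactly for the linear kernel.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] != model.alpha.size:
        raise ValueError("X_train rows do not match training size")
    return model.theta * (X_train.T @ model.alpha)


# ---------------------------------------------------------------------------
# GP classification (probit likelihood, Laplace approximation)
# ---------------------------------------------------------------------------


@dataclass
class GPCModel:
    theta: float
    f_hat: np.ndarray  # posterior mode of latent function
    grad: np.ndarray  # d log p(y|f) at the mode
    w_sqrt: np.ndarray  # sqrt of negative Hessian diagonal
    L: np.ndarray  # chol(I + W^1/2 K W^1/2)
    labels: np.ndarray  # training labels in {-1, +1}
    jitter: float
    train_index: np.ndarray | None = None
    log_evidence: float = float("-inf")
    classes: tuple = field(default_factory=lambda: (-1, 1))


def _probit_moments(f: np.ndarray, y: np.ndarray):
    """(log lik, gradient, negative Hessian diag) of the probit likelihood."""
    z = y * f
    log_phi = stats.norm.logcdf(z)
    ratio = np.exp(stats.norm.logpdf(z) - log_phi)  # phi(z)/Phi(z), stable
    grad = y * ratio
    w = ratio**2 + z * ratio  # -d2 log Phi(z) / df2, always > 0
    return float(np.sum(log_phi)), grad, w


def _laplace_mode(Kt: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Newton iteration for the posterior mode (RW Algorithm 3.1)."""
    n = y.size
    f = np.zeros(n)
    log_ev = -np.inf
    for _ in range(max_iter):
        loglik, grad, w = _probit_moments(f, y)
        w_sqrt = np.sqrt(w)
        B = np.eye(n) + w_sqrt[:, None] * Kt * w_sqrt[None, :]
        L = cholesky(B, lower=True)
        b = w * f + grad
        a = b - w_sqrt * cho_solve((L, True), w_sqrt * (Kt @ b))
        f_new = Kt @ a
        new_ev = (
            -0.5 * a @ f_new
            + _probit_moments(f_new, y)[0]
            - np.sum(np.log(np.diag(L)))
        )
        if abs(new_ev - log_ev) < 1e-10:
            f = f_new
            log_ev = new_ev
            break
        f, log_ev = f_new, new_ev
    loglik, grad, w = _probit_moments(f, y)
    w_sqrt = np.sqrt(w)
    B = np.eye(n) + w_sqrt[:, None] * Kt * w_sqrt[None, :]
    L = cholesky(B, lower=True)
    return f, grad, w_sqrt, L, float(log_ev)


def _as_pm1(labels: np.ndarray) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes in training labels, got {classes}")
    return np.where(labels == classes[1], 1.0, -1.0), tuple(classes)


def fit_gpc(
    K: np.ndarray,
    labels: np.ndarray,
    theta: float | None = None,
    train_index: np.ndarray | None = None,
) -> GPCModel:
    """Fit a probit-Laplace GPC; ``theta`` selected by Laplace evidence over
    a log grid when not supplied."""
    K = np.asarray(K, dtype=float)
    y, classes = _as_pm1(labels)
    jitter = _jitter(K)
    k_scale = max(float(np.mean(np.diag(K))), 1e-300)
    if theta is not None:
        thetas = [theta]
    else:
        thetas = np.logspace(
            np.log10(GRID_SPAN[0]), np.log10(GRID_SPAN[1]), GRID_SIZE
        ) / k_scale
    best = None
    for th in thetas:
        Kt = th * K + jitter * np.eye(K.shape[0])
        f, grad, w_sqrt, L, log_ev = _laplace_mode(Kt, y)
        if best is None or log_ev > best.log_evidence:
            best = GPCModel(
                theta=float(th), f_hat=f, grad=grad, w_sqrt=w_sqrt, L=L,
                labels=y, jitter=jitter, train_index=train_index,
                log_evidence=log_ev, classes=classes,
            )
    return best


def predict_gpc(
    model: GPCModel, K_test_train: np.ndarray, k_test_diag: np.ndarray
) -> np.ndarray:
    """Predictive probability of the positive (second) class per test row.

    ``k_test_diag`` holds the raw linear-kernel self-products k(x*, x*),
    needed for the latent predictive variance.
    """
    K_test_train = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    k_star = model.theta * K_test_train  # n_test x n_train
    f_mean = k_star @ model.grad
    v = solve_triangular(
        model.L, (model.w_sqrt[None, :] * k_star).T, lower=True
    )
    prior_var = model.theta * np.asarray(k_test_diag, dtype=float) + model.jitter
    f_var = np.clip(prior_var - np.sum(v**2, axis=0), 1e-12, None)
    return stats.norm.cdf(f_mean / np.sqrt(1.0 + f_var))
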