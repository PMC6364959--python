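"""Elastic-net regression solved by cyclic coordinate descent.

The objective is implemented exactly as displayed in the source method:

    f(b0, beta) = ||y - b0 - X beta||^2
                  + alpha * lam * ||beta||_2^2
                  + (lam / 2) * (1 - alpha) * ||beta||_1

Note the non-standard parameterization: ``alpha`` multiplies the ridge
penalty and ``(1 - alpha)/2`` the lasso penalty, and the squared error
carries no 1/(2n) scaling — most libraries (e.g. glmnet/scikit-learn)
use the reverse mixing plus sample-size scaling, so a given (alpha,
lam) here corresponds to ridge weight ``alpha*lam`` and lasso weight
``lam*(1-alpha)/2`` in absolute terms. The intercept is never
penalized. Defaults are alpha = 0.3, lam = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ALPHA = 0.3
DEFAULT_LAMBDA = 0.05


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the iteration cap."""


@dataclass(frozen=True)
class ModelHyperparams:
    alpha: float = DEFAULT_ALPHA
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0.0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class ModelCoefficients:
    coef: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] | None = None
    n_iter: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def elasticnet_objective(
    X: np.ndarray,
    y: np.ndarray,
    coef: np.ndarray,
    intercept: float,
    alpha: float,
    lam: float,
) -> float:
    """Value of the penalized objective at (intercept, coef)."""
    resid = np.asarray(y, float) - np.asarray(X, float) @ coef - intercept
    return float(
        resid @ resid
        + alpha * lam * float(coef @ coef)
        + (lam / 2.0) * (1.0 - alpha) * float(np.abs(coef).sum())
    )


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_kernel(G, c, diag, denom, thresh, beta, max_iter, tol):
    """Cyclic coordinate-descent sweeps on the Gram system.

    Mutates ``beta`` in place; returns the iteration count on
    convergence, -1 otherwise. Written in plain loops so it can be
    numba-compiled; the interpreted version is the fallback.
    """
    p = G.shape[0]
    Gb = np.zeros(p)
    for iteration in range(1, max_iter + 1):
        max_change = 0.0
        for j in range(p):
            b_old = beta[j]
            rho = c[j] - Gb[j] + diag[j] * b_old
            if denom[j] <= 0.0:
                b_new = 0.0
            else:
                if rho > thresh:
                    z = rho - thresh
                elif rho < -thresh:
                    z = rho + thresh
                else:
                    z = 0.0
                b_new = z / denom[j]
            if b_new != b_old:
                delta = b_new - b_old
                for k in range(p):
                    Gb[k] += G[k, j] * delta
                beta[j] = b_new
                change = abs(delta)
                if change > max_change:
                    max_change = change
        if max_change < tol:
            return iteration
    return -1


try:  # optional: ~100x faster sweeps when numba is installed
    from numba import njit

    _cd_kernel_fast = njit(cache=False)(_cd_kernel)
except ImportError:  # pragma: no cover - exercised only without numba
    _cd_kernel_fast = _cd_kernel


def fit_elasticnet(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: ModelHyperparams | None = None,
    *,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    feature_names: tuple[str, ...] | None = None,
) -> ModelCoefficients:
    """Minimize the penalized squared error by cyclic coordinate descent.

    The intercept is handled by centering (equivalent to an unpenalized
    coordinate); Gram-matrix updates make each sweep O(p^2). Raises on
    non-finite inputs and on non-convergence.
    """
    if hyperparams is None:
        hyperparams = ModelHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (impute before fitting)")
    n, p = X.shape
    if n == 0:
        raise ValueError("cannot fit on an empty design matrix")
    alpha, lam = hyperparams.alpha, hyperparams.lam

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    G = Xc.T @ Xc
    c = Xc.T @ yc
    diag = np.diag(G).copy()
    denom = diag + alpha * lam
    thresh = lam * (1.0 - alpha) / 4.0

    beta = np.zeros(p)
    n_iter = int(
        _cd_kernel_fast(
            np.ascontiguousarray(G), c, diag, denom, float(thresh), beta,
            int(max_iter), float(tol),
        )
    )
    if n_iter < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} iterations"
        )
    intercept = y_mean - float(x_mean @ beta)
    return ModelCoefficients(
        coef=beta, intercept=intercept, feature_names=feature_names, n_iter=n_iter
    )
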