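"""Metric Learning for Kernel Regression (MLKR).

MLKR learns a Mahalanobis metric
``d_M(x, x') = sqrt((x - x')^T M (x - x'))`` with ``M = A^T A`` by
minimizing the leave-one-out kernel-regression squared error

    L(A) = sum_i (y_i - f_LOO(x_i))^2,
    f_LOO(x_i) = sum_{j != i} y_j k_ij / sum_{j != i} k_ij,
    k_ij = exp(-d_M(x_i, x_j)^2 / sigma^2).

The rank of M is limited through the shape of A (p x d with p <= d),
which caps the cost of the learned transform like a supervised PCA.
The Gaussian normalization prefactor cancels in the LOO ratio and is
omitted.  sigma is fixed to 1 by default: after standardizing the
features it is absorbable into the overall scale of A.

A config switch ``exponent="literal"`` evaluates ``exp(-d_M / sigma^2)``
(the unsquared form) instead of the standard squared-distance RBF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from molknn._util import substream

__all__ = [
    "MahalanobisMetric",
    "MLKRFitReport",
    "mahalanobis_distance",
    "mlkr_loss",
    "mlkr_gradient",
    "mlkr_fit",
    "transform",
]

logger = logging.getLogger(__name__)


@dataclass
class MahalanobisMetric:
    """Rank-limited Mahalanobis metric, ``d_M(x, x') = ||A (x - x')||``."""

    A: np.ndarray  # (p, d)
    sigma: float = 1.0
    rank_limit: int | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.rank_limit is None:
            self.rank_limit = self.A.shape[0]

    @property
    def M(self) -> np.ndarray:
        return self.A.T @ self.A


@dataclass
class MLKRFitReport:
    loss_trajectory: np.ndarray
    n_iterations: int
    converged: bool
    subsample_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def mahalanobis_distance(
    metric: MahalanobisMetric, X: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Distance matrix ``D_ij = ||A (x_i - z_j)||_2``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    d = metric.A.shape[1]
    if X.shape[1] != d or Z.shape[1] != d:
        raise ValueError(f"expected {d}-dimensional rows")
    return cdist(X @ metric.A.T, Z @ metric.A.T)


def transform(metric: MahalanobisMetric, X: np.ndarray) -> np.ndarray:
    """Map points into the learned space; Euclidean distances there equal d_M."""
    return np.atleast_2d(np.asarray(X, dtype=float)) @ metric.A.T


def _loo_terms(A, X, y, sigma, exponent):
    """Stabilized LOO kernel weights, sums and predictions.

    Row-wise the smallest (off-diagonal) exponent argument is subtracted
    before exponentiation; the LOO ratio is invariant to that row scaling,
    so the nearest off-diagonal kernel entry is always exp(0) = 1 and the
    normalizing sums never underflow.
    """
    T = X @ A.T
    d2 = cdist(T, T, "sqeuclidean")
    if exponent == "squared":
        E = d2 / sigma**2
    elif exponent == "literal":
        E = np.sqrt(np.maximum(d2, 0.0)) / sigma**2
    else:
        raise ValueError("exponent must be 'squared' or 'literal'")
    np.fill_diagonal(E, np.inf)
    row_min = E.min(axis=1)
    K = np.exp(-(E - row_min[:, None]))
    np.fill_diagonal(K, 0.0)
    S = K.sum(axis=1)
    yhat = np.empty_like(np.asarray(y, dtype=float))
    ok = S > 0
    yhat[ok] = (K[ok] @ y) / S[ok]
    if not np.all(ok):  # all neighbours at infinite distance: NN fallback
        logger.warning("LOO kernel sums underflowed for %d points; "
                       "falling back to nearest-neighbour labels", (~ok).sum())
        d2_safe = d2.copy()
        np.fill_diagonal(d2_safe, np.inf)
        yhat[~ok] = np.asarray(y)[np.argmin(d2_safe[~ok], axis=1)]
        S[~ok] = 1.0
    return d2, K, S, yhat


def mlkr_loss(
    A: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = 1.0,
    exponent: str = "squared",
) -> float:
    """Leave-one-out kernel-regression squared error of the metric A."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least two points")
    _, _, _, yhat = _loo_terms(np.atleast_2d(A), X, y, sigma, exponent)
    return float(np.sum((y - yhat) ** 2))


def mlkr_gradient(
    A: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = 1.0,
    exponent: str = "squared",
) -> np.ndarray:
    """Analytic gradient of :func:`mlkr_loss` with respect to A.

    Derivation (squared form): with normalized LOO weights
    ``k_ij / S_i`` the chain rule gives

        dL/dA = (4 / sigma^2) A sum_{i != j} P_ij (x_i - x_j)(x_i - x_j)^T,
        P_ij = (yhat_i - y_i)(yhat_i - y_j) k_ij / S_i,

    which is evaluated as ``A X^T (diag(r) + diag(c) - P - P^T) X`` with
    r, c the row/column sums of P.  The literal (unsquared) exponent picks
    up a factor 1/(2 d_ij) per pair instead.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least two points")
    d2, K, S, yhat = _loo_terms(A, X, y, sigma, exponent)
    resid = yhat - y
    P = (resid[:, None] * (yhat[:, None] - y[None, :])) * K / S[:, None]
    np.fill_diagonal(P, 0.0)
    if exponent == "squared":
        coeff = 4.0 / sigma**2
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_d = np.where(d2 > 0, 1.0 / np.sqrt(np.maximum(d2, 0.0)), 0.0)
        P = P * (0.5 * inv_d)
        coeff = 4.0 / sigma**2
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    L = -(P + P.T)
    L[np.diag_indices_from(L)] += r + c
    return coeff * (A @ (X.T @ (L @ X)))


def _pca_init(Xs: np.ndarray, rank_limit: int) -> np.ndarray:
    """Initialize A from the top principal directions, scaled to unit variance."""
    n = Xs.shape[0]
    Xc = Xs - Xs.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Vt = Vt[:rank_limit]
    if Vt.shape[0] < rank_limit:  # n - 1 < rank_limit: pad with zero rows
        Vt = np.vstack([Vt, np.zeros((rank_limit - Vt.shape[0], Xs.shape[1]))])
        s = np.concatenate([s, np.zeros(rank_limit - s.size)])
    sd = s[:rank_limit] / np.sqrt(max(n - 1, 1))
    sd = np.where(sd > 1e-12, sd, 1.0)
    return Vt / sd[:, None]


def mlkr_fit(
    X: np.ndarray,
    y: np.ndarray,
    rank_limit: int = 50,
    subsample_cap: int | None = 25000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    sigma: float = 1.0,
    standardize: bool = True,
    exponent: str = "squared",
) -> tuple[MahalanobisMetric, MLKRFitReport]:
    """Learn a rank-limited Mahalanobis metric by L-BFGS on the MLKR loss.

    Parameters
    ----------
    rank_limit
        Number of rows of A (rank of M); 50 is enough in practice and
        caps the optimization cost.
    subsample_cap
        Optimize on a seeded random subsample (without replacement) of at
        most this many points; the learned metric is then applied to all
        data.  ``None`` disables subsampling.
    seed
        Master seed; subsampling uses a named substream.
    tol
        Relative loss-decrease convergence threshold.
    standardize
        Standardize features to zero mean / unit variance before learning;
        the scaling is folded into the returned A so the metric applies to
        raw features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two points")
    if rank_limit > d:
        raise ValueError(f"rank_limit {rank_limit} exceeds dimensionality {d}")
    if subsample_cap is not None and n > subsample_cap:
        rng = substream(seed, "mlkr-subsample")
        sub = np.sort(rng.choice(n, size=subsample_cap, replace=False))
    else:
        sub = np.arange(n)

    if standardize:
        mu = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 1e-12, scale, 1.0)
    else:
        mu = np.zeros(d)
        scale = np.ones(d)
    Xs = (X - mu) / scale
    Xfit, yfit = Xs[sub], y[sub]

    A0 = _pca_init(Xs, rank_limit)
    shape = A0.shape

    def fun(a_flat):
        A = a_flat.reshape(shape)
        loss = mlkr_loss(A, Xfit, yfit, sigma, exponent)
        grad = mlkr_gradient(A, Xfit, yfit, sigma, exponent)
        return loss, grad.ravel()

    trajectory = [mlkr_loss(A0, Xfit, yfit, sigma, exponent)]

    def cb(a_flat):
        trajectory.append(mlkr_loss(a_flat.reshape(shape), Xfit, yfit, sigma, exponent))

    res = minimize(
        fun,
        A0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    A_opt = res.x.reshape(shape)
    if mlkr_loss(A_opt, Xfit, yfit, sigma, exponent) > trajectory[0]:
        A_opt = A0  # never return something worse than the initialization
    A_eff = A_opt / scale[None, :]
    metric = MahalanobisMetric(A=A_eff, sigma=sigma, rank_limit=rank_limit)
    report = MLKRFitReport(
        loss_trajectory=np.asarray(trajectory),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        subsample_indices=sub,
    )
    return metric, report
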