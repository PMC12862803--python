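"""Nearest-neighbour search, weighted k-NN regression and uncertainty.

Prediction is a convex combination of neighbour labels:

    f(x) = sum_{i in N_k(x, d)} w_i y_i / sum w_i

with uniform weights (plain mean) or reciprocal-distance weights
``w_i = 1/d_i``.  Zero distances take the limit of reciprocal weighting:
the prediction is the mean over the zero-distance neighbours.

Leave-one-out tuning of k uses the (k+1)-NN scaling identity for uniform
weights: querying each training point against the full index with k+1
neighbours (self included) gives

    f_LOO,k(x_i) = ((k+1) f_{k+1}(x_i) - y_i) / k,

so one distance-matrix pass prices every k at once.

The neighbour label set also carries the predictive uncertainty: its
empirical quantiles estimate percentiles of the target, and a
calibration curve compares those nominal percentiles with the observed
fraction of test labels falling below them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from molknn.mlkr import MahalanobisMetric

__all__ = [
    "NeighborIndex",
    "NeighborPrediction",
    "build_index",
    "knn_predict",
    "knn_predict_batch",
    "mlkr_kernel_regression_predict",
    "loo_knn_predictions",
    "tune_k_loo",
    "neighbor_quantiles",
    "calibration_curve",
]


@dataclass
class NeighborPrediction:
    """Point estimate plus the neighbour set it was built from."""

    estimate: float
    neighbor_ids: np.ndarray
    neighbor_distances: np.ndarray
    neighbor_labels: np.ndarray
    quantiles: dict = field(default_factory=dict)


class NeighborIndex:
    """Queryable nearest-neighbour index.

    Modes: ``euclidean`` (points as-is), ``mahalanobis`` (points
    pre-transformed by the metric's A), ``kernel_induced`` (no
    coordinates; queries pass precomputed distance rows).  Backends:
    ``brute`` (stable argsort, ties broken by ascending stored index) or
    ``tree`` (sklearn KDTree; true metric coordinates only).
    """

    def __init__(self, points=None, distances=None, mode="euclidean",
                 backend="brute", metric: MahalanobisMetric | None = None):
        if mode not in ("euclidean", "mahalanobis", "kernel_induced"):
            raise ValueError(f"unknown distance mode {mode!r}")
        if backend not in ("brute", "tree"):
            raise ValueError(f"unknown backend {backend!r}")
        self.mode = mode
        self.backend = backend
        self.metric = metric
        self._tree = None
        if mode == "kernel_induced":
            if backend == "tree":
                raise ValueError(
                    "tree backend requires explicit coordinates; "
                    "kernel-induced distances have none"
                )
            if distances is None:
                raise ValueError("kernel_induced mode needs a distance matrix")
            D = np.asarray(distances, dtype=float)
            self._train_distances = D
            self.n = D.shape[0]
            self.points = None
        else:
            if points is None:
                raise ValueError(f"{mode} mode needs stored points")
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            if mode == "mahalanobis":
                if metric is None:
                    raise ValueError("mahalanobis mode needs a MahalanobisMetric")
                pts = pts @ metric.A.T
            self.points = pts
            self.n = pts.shape[0]
            self._train_distances = None
            if backend == "tree":
                from sklearn.neighbors import KDTree

                self._tree = KDTree(pts)

    def _prepare_query(self, X):
        if self.mode == "kernel_induced":
            return np.atleast_2d(np.asarray(X, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mode == "mahalanobis":
            X = X @ self.metric.A.T
        return X

    def query(self, X, k: int):
        """k nearest stored points for each query row.

        In ``kernel_induced`` mode ``X`` is a (m, n_train) matrix of
        precomputed distances.  Returns ``(distances, indices)`` with rows
        sorted ascending; exact ties are broken by ascending index.
        """
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} not in [1, {self.n}]")
        Q = self._prepare_query(X)
        if self.mode == "kernel_induced":
            D = Q
            if D.shape[1] != self.n:
                raise ValueError("distance rows must have one column per stored point")
        elif self.backend == "tree":
            dist, idx = self._tree.query(Q, k=k)
            # normalize tie order inside the returned set: (distance, index)
            order = np.lexsort((idx, dist), axis=1)
            rows = np.arange(Q.shape[0])[:, None]
            return dist[rows, order], idx[rows, order]
        else:
            D = cdist(Q, self.points)
        idx = np.argsort(D, axis=1, kind="stable")[:, :k]
        rows = np.arange(D.shape[0])[:, None]
        return D[rows, idx], idx


def build_index(points=None, distances=None, mode="euclidean",
                backend="brute", metric=None) -> NeighborIndex:
    """Construct a :class:`NeighborIndex` (see the class for semantics)."""
    return NeighborIndex(points=points, distances=distances, mode=mode,
                         backend=backend, metric=metric)


def _weighted_estimates(dist, labels, weighting):
    """Estimates for neighbour blocks ``dist``/``labels`` of shape (m, k)."""
    if weighting == "uniform":
        return labels.mean(axis=1)
    if weighting != "reciprocal":
        raise ValueError(f"unknown weighting {weighting!r}")
    est = np.empty(dist.shape[0])
    zero = dist <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    if np.any(~any_zero):
        rows = ~any_zero
        est[rows] = (w[rows] * labels[rows]).sum(axis=1) / w[rows].sum(axis=1)
    if np.any(any_zero):
        for i in np.where(any_zero)[0]:
            est[i] = labels[i, zero[i]].mean()
    return est


def knn_predict(
    index: NeighborIndex,
    y: np.ndarray,
    x,
    k: int,
    weighting: str = "reciprocal",
) -> NeighborPrediction:
    """Weighted k-NN prediction for a single query point (or distance row)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != index.n:
        raise ValueError("len(y) must equal the number of stored points")
    dist, idx = index.query(np.atleast_2d(x), k)
    labels = y[idx]
    est = _weighted_estimates(dist, labels, weighting)
    return NeighborPrediction(
        estimate=float(est[0]),
        neighbor_ids=idx[0],
        neighbor_distances=dist[0],
        neighbor_labels=labels[0],
    )


def knn_predict_batch(
    index: NeighborIndex,
    y: np.ndarray,
    X,
    k: int,
    weighting: str = "reciprocal",
    return_neighbors: bool = False,
):
    """Vectorized k-NN prediction for many queries.

    Returns the estimates, or ``(estimates, distances, indices)`` when
    ``return_neighbors`` is set.
    """
    y = np.asarray(y, dtype=float).ravel()
    dist, idx = index.query(X, k)
    est = _weighted_estimates(dist, y[idx], weighting)
    if return_neighbors:
        return est, dist, idx
    return est


def mlkr_kernel_regression_predict(
    metric: MahalanobisMetric,
    X_train: np.ndarray,
    y: np.ndarray,
    X_query,
    sigma: float | None = None,
) -> np.ndarray:
    """Kernel regression with the learned metric: softmax-of-distance weights.

    ``f(x) = sum_j w_j y_j`` with
    ``w_j = k(d_M(x, x_j)) / sum_l k(d_M(x, x_l))`` over *all* training
    points, ``k(d) = exp(-d^2 / sigma^2)``.  The weight ratio is
    stabilized by subtracting the row-wise minimal squared distance, which
    also covers the all-underflow case with the nearest neighbour's label.
    """
    from molknn.mlkr import mahalanobis_distance

    y = np.asarray(y, dtype=float).ravel()
    if sigma is None:
        sigma = metric.sigma
    D = mahalanobis_distance(metric, np.atleast_2d(X_query), X_train)
    E = D**2 / sigma**2
    E = E - E.min(axis=1, keepdims=True)
    K = np.exp(-E)
    return (K @ y) / K.sum(axis=1)


def loo_knn_predictions(
    X_or_index,
    y: np.ndarray,
    k: int,
    weighting: str = "uniform",
) -> np.ndarray:
    """Leave-one-out k-NN predictions for every training point.

    Uniform weights use the (k+1)-NN scaling identity
    ``f_LOO,k(x_i) = ((k+1) f_{k+1}(x_i) - y_i) / k`` on the
    self-including neighbour list; reciprocal weights drop the self
    neighbour and weight the next k.
    """
    y = np.asarray(y, dtype=float).ravel()
    index = (
        X_or_index
        if isinstance(X_or_index, NeighborIndex)
        else build_index(points=X_or_index)
    )
    n = index.n
    if not 1 <= k < n:
        raise ValueError(f"k={k} not in [1, {n - 1}]")
    if index.mode == "kernel_induced":
        dist, idx = index.query(index._train_distances, k + 1)
    else:
        dist, idx = _self_query(index, k + 1)
    labels = y[idx]
    if weighting == "uniform":
        f_incl = labels.mean(axis=1)
        return ((k + 1) * f_incl - y) / k
    if weighting != "reciprocal":
        raise ValueError(f"unknown weighting {weighting!r}")
    m = idx.shape[1]
    self_mask = idx == np.arange(n)[:, None]
    first_self = np.where(self_mask.any(axis=1), self_mask.argmax(axis=1), m - 1)
    keep = np.ones_like(idx, dtype=bool)
    keep[np.arange(n), first_self] = False
    d_loo = dist[keep].reshape(n, m - 1)
    l_loo = labels[keep].reshape(n, m - 1)
    return _weighted_estimates(d_loo, l_loo, "reciprocal")


def tune_k_loo(
    X_or_index,
    y: np.ndarray,
    k_grid,
    weighting: str = "uniform",
) -> tuple[int, dict[int, float]]:
    """Leave-one-out tuning of k from one distance pass.

    Uniform weights use the (k+1)-NN scaling shortcut; reciprocal weights
    drop the self neighbour (its zero distance would degenerate the
    weights) and use the next k neighbours.  Returns the LOO-MAE-minimal
    k, ties resolved toward the smaller k.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    y = np.asarray(y, dtype=float).ravel()
    index = (
        X_or_index
        if isinstance(X_or_index, NeighborIndex)
        else build_index(points=X_or_index)
    )
    n = index.n
    kmax = max(k_grid)
    if kmax >= n:
        raise ValueError(f"max k={kmax} must be < n={n}")
    if index.mode == "kernel_induced":
        dist, idx = index.query(index._train_distances, kmax + 1)
    else:
        dist, idx = _self_query(index, kmax + 1)
    labels = y[idx]
    loo_mae: dict[int, float] = {}
    if weighting == "uniform":
        csum = np.cumsum(labels, axis=1)
        for k in k_grid:
            f_incl = csum[:, k] / (k + 1)  # self-including (k+1)-NN mean
            f_loo = ((k + 1) * f_incl - y) / k
            loo_mae[k] = float(np.mean(np.abs(y - f_loo)))
    elif weighting == "reciprocal":
        # drop self from each neighbour list
        m = idx.shape[1]
        self_mask = idx == np.arange(n)[:, None]
        first_self = np.where(
            self_mask.any(axis=1), self_mask.argmax(axis=1), m - 1
        )
        keep = np.ones_like(idx, dtype=bool)
        keep[np.arange(n), first_self] = False
        d_loo = dist[keep].reshape(n, m - 1)
        l_loo = labels[keep].reshape(n, m - 1)
        for k in k_grid:
            est = _weighted_estimates(d_loo[:, :k], l_loo[:, :k], "reciprocal")
            loo_mae[k] = float(np.mean(np.abs(y - est)))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    best_k = min(k_grid, key=lambda k: (loo_mae[k], k))
    return best_k, loo_mae


def _self_query(index: NeighborIndex, k: int):
    """Query an index with its own stored points (self included in results).

    Stored points are already in query space (the mahalanobis transform
    was applied at build time), so the distance computation bypasses
    ``_prepare_query`` to avoid re-applying A.
    """
    if index.points is None:
        raise ValueError("index stores no coordinates")
    pts = index.points
    if index.backend == "tree":
        dist, idx = index._tree.query(pts, k=k)
        order = np.lexsort((idx, dist), axis=1)
        rows = np.arange(pts.shape[0])[:, None]
        return dist[rows, order], idx[rows, order]
    D = cdist(pts, pts)
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]
    rows = np.arange(D.shape[0])[:, None]
    return D[rows, idx], idx


def neighbor_quantiles(
    prediction_or_labels,
    percentiles,
    method: str = "linear",
) -> dict[float, float]:
    """Empirical quantiles of the (unweighted) neighbour labels.

    ``method`` is any numpy quantile method; ``"linear"`` matches the
    classic interpolation definition, while ``"weibull"`` uses the
    (k+1)p plotting positions whose coverage matches the nominal level
    and is what the calibration workflow uses.  When given a
    :class:`NeighborPrediction` the quantile map is also stored on it.
    """
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("percentile list must be nonempty")
    if isinstance(prediction_or_labels, NeighborPrediction):
        labels = prediction_or_labels.neighbor_labels
    else:
        labels = np.asarray(prediction_or_labels, dtype=float).ravel()
    if labels.size < 1:
        raise ValueError("need at least one neighbour label")
    q = {
        float(p): float(np.quantile(labels, p / 100.0, method=method))
        for p in percentiles
    }
    if isinstance(prediction_or_labels, NeighborPrediction):
        prediction_or_labels.quantiles.update(q)
    return q


def calibration_curve(quantile_sets, y_true, percent_grid) -> np.ndarray:
    """Observed fraction of true labels below each estimated percentile.

    ``quantile_sets`` is either an (n_items, n_percentiles) array aligned
    with ``percent_grid`` or a list of per-item percentile->value maps.
    Well-calibrated quantiles put a fraction ~p/100 of the truth below
    the p-th percentile.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    grid = [float(p) for p in percent_grid]
    if isinstance(quantile_sets, np.ndarray):
        Q = np.atleast_2d(quantile_sets)
    else:
        try:
            Q = np.array([[qs[p] for p in grid] for qs in quantile_sets])
        except KeyError as exc:
            raise ValueError(f"percentile {exc} missing from a quantile set")
    if Q.shape != (y_true.size, len(grid)):
        raise ValueError("quantile table shape does not match y_true and grid")
    return (y_true[:, None] <= Q).mean(axis=0)
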