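"""Delta-learning, cross-validation, learning curves and hyperparameter tuning.

The harness compares five model families on a labelled structure dataset:

* ``krr`` — kernel ridge regression with the extensive atomic kernel on
  local descriptors (the accuracy baseline),
* ``knn_euclidean`` — k-NN with Euclidean distance on global descriptors,
* ``knn_mlkr`` — k-NN with an MLKR-learned Mahalanobis metric,
* ``knn_kernel_distance`` — k-NN with the kernel-induced distance of the
  extensive kernel,
* ``kernel_regression_mlkr`` — softmax-weighted kernel regression with
  the MLKR metric (the comparator that shows what the hard k cutoff
  adds).

Targets are either the high-level label directly (``direct``) or the
residual between the two label levels (``delta``); in delta mode the
final prediction adds the low-level label of the test item back.

All randomness flows from one master seed through named substreams.
Timing is recorded but never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from molknn._util import substream
from molknn.descriptors import (
    ManyBodyParams,
    global_matrix,
    local_representations,
)
from molknn.kernels import (
    KernelSpec,
    kernel_induced_distance,
    kernel_matrix,
    kernel_self_similarities,
    median_pairwise_distance,
)
from molknn.knn import build_index, knn_predict_batch, mlkr_kernel_regression_predict
from molknn.krr import krr_fit, krr_predict
from molknn.mlkr import mlkr_fit
from molknn.structures import LabeledDataset, format_composition

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "EvaluationPlan",
    "Features",
    "mae",
    "delta_targets",
    "cross_validate",
    "extrapolation_split",
    "tune_krr_hyperparams",
    "tune_knn_k",
    "fit_predict",
    "plot_learning_curves",
    "plot_calibration",
]

MODEL_NAMES = (
    "krr",
    "knn_euclidean",
    "knn_mlkr",
    "knn_kernel_distance",
    "kernel_regression_mlkr",
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters.

    ``sigma=None`` uses the median-pairwise-distance heuristic computed on
    the training representations.  ``k=10`` is the recommended first
    guess when tuning is skipped.
    """

    name: str = "knn_mlkr"
    k: int = 10
    weighting: str = "reciprocal"
    sigma: float | None = None
    lambda_: float = 1e-8
    rank_limit: int = 50
    mlkr_subsample_cap: int | None = 25000
    mlkr_max_iter: int = 200
    backend: str = "brute"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; one of {MODEL_NAMES}")


@dataclass
class EvaluationPlan:
    """Cross-validated learning-curve protocol.

    Five folds by default; the test fold size is fixed while training
    sets of each requested size are subsampled from the remaining 80%.
    """

    model: ModelSpec = field(default_factory=ModelSpec)
    n_folds: int = 5
    train_sizes: tuple[int, ...] = ()
    seed: int = 0
    target_mode: str = "direct"  # "direct" | "delta"
    descriptor: ManyBodyParams | None = None

    def __post_init__(self) -> None:
        if self.target_mode not in ("direct", "delta"):
            raise ValueError("target_mode must be 'direct' or 'delta'")


def mae(y_true, y_pred) -> float:
    """Mean absolute error, ``(1/n) sum |y_i - f_i|``."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.mean(np.abs(y_true - y_pred)))


def delta_targets(dataset: LabeledDataset) -> np.ndarray:
    """Residual between the two label levels, ``y_high - y_low``."""
    if dataset.y_low is None:
        raise ValueError("delta-learning requires low-level labels (y_low)")
    if dataset.y_high is None:
        raise ValueError("dataset has no high-level labels")
    return dataset.y_high - dataset.y_low


class Features:
    """Lazily computed, dataset-wide descriptor views.

    The element schema is built from the union over the whole dataset
    before any train/test split, so train and test vectors always align.
    """

    def __init__(self, dataset: LabeledDataset, params: ManyBodyParams | None = None):
        self.dataset = dataset
        if params is None:
            params = ManyBodyParams()
        if not params.element_set:
            params = replace(params, element_set=tuple(dataset.element_set))
        self.params = params
        self._local = None
        self._global = None

    @property
    def local(self):
        if self._local is None:
            self._local = local_representations(self.dataset, self.params)
        return self._local

    @property
    def global_(self) -> np.ndarray:
        if self._global is None:
            self._global = global_matrix(self.dataset, locals_=self.local)
        return self._global


def _default_sigma(model: ModelSpec, feats: Features, idx_train) -> float:
    if model.sigma is not None:
        return model.sigma
    if model.name in ("krr", "knn_kernel_distance"):
        reps = [feats.local[i] for i in idx_train]
        return median_pairwise_distance(reps)
    return median_pairwise_distance(feats.global_[idx_train])


def fit_predict(
    model: ModelSpec,
    feats: Features,
    y_target: np.ndarray,
    idx_train,
    idx_test,
    seed: int = 0,
):
    """Fit one model on training indices and predict the test indices.

    Returns ``(y_pred, fit_seconds, predict_seconds)`` where ``y_pred``
    predicts the target (the residual in delta mode).
    """
    idx_train = np.asarray(idx_train, dtype=int)
    idx_test = np.asarray(idx_test, dtype=int)
    y_tr = np.asarray(y_target, dtype=float)[idx_train]

    if model.name == "krr":
        sigma = _default_sigma(model, feats, idx_train)
        spec = KernelSpec(kind="extensive_atomic", sigma=sigma)
        reps_tr = [feats.local[i] for i in idx_train]
        reps_te = [feats.local[i] for i in idx_test]
        t0 = time.perf_counter()
        K = kernel_matrix(reps_tr, reps_tr, spec)
        fitted = krr_fit(K, y_tr, model.lambda_, spec=spec)
        t1 = time.perf_counter()
        K_te = kernel_matrix(reps_te, reps_tr, spec)
        pred = krr_predict(fitted, K_te)
        t2 = time.perf_counter()
        return pred, t1 - t0, t2 - t1

    if model.name == "knn_kernel_distance":
        sigma = _default_sigma(model, feats, idx_train)
        spec = KernelSpec(kind="extensive_atomic", sigma=sigma)
        reps_tr = [feats.local[i] for i in idx_train]
        reps_te = [feats.local[i] for i in idx_test]
        t0 = time.perf_counter()
        diag_tr = kernel_self_similarities(reps_tr, spec)
        index = build_index(
            distances=np.zeros((len(idx_train), len(idx_train))),
            mode="kernel_induced",
        )
        t1 = time.perf_counter()
        K_cross = kernel_matrix(reps_te, reps_tr, spec)
        diag_te = kernel_self_similarities(reps_te, spec)
        D = kernel_induced_distance(diag_te, diag_tr, K_cross)
        pred = knn_predict_batch(index, y_tr, D, model.k, model.weighting)
        t2 = time.perf_counter()
        return pred, t1 - t0, t2 - t1

    G = feats.global_
    X_tr, X_te = G[idx_train], G[idx_test]
    if model.name == "knn_euclidean":
        t0 = time.perf_counter()
        index = build_index(points=X_tr, mode="euclidean", backend=model.backend)
        t1 = time.perf_counter()
        pred = knn_predict_batch(index, y_tr, X_te, model.k, model.weighting)
        t2 = time.perf_counter()
        return pred, t1 - t0, t2 - t1

    # MLKR-based variants
    rank = min(model.rank_limit, X_tr.shape[1])
    t0 = time.perf_counter()
    metric, _ = mlkr_fit(
        X_tr,
        y_tr,
        rank_limit=rank,
        subsample_cap=model.mlkr_subsample_cap,
        seed=seed,
        max_iter=model.mlkr_max_iter,
    )
    t1 = time.perf_counter()
    if model.name == "knn_mlkr":
        index = build_index(points=X_tr, mode="mahalanobis",
                            backend=model.backend, metric=metric)
        pred = knn_predict_batch(index, y_tr, X_te, model.k, model.weighting)
    else:  # kernel_regression_mlkr
        pred = mlkr_kernel_regression_predict(metric, X_tr, y_tr, X_te)
    t2 = time.perf_counter()
    return pred, t1 - t0, t2 - t1


def _targets_for_mode(dataset: LabeledDataset, mode: str) -> np.ndarray:
    if mode == "delta":
        return delta_targets(dataset)
    if dataset.y_high is None:
        raise ValueError("dataset has no labels")
    return dataset.y_high


def _final_prediction(dataset, mode, idx_test, target_pred):
    if mode == "delta":
        return dataset.y_low[np.asarray(idx_test, int)] + target_pred
    return target_pred


def default_train_sizes(n: int, n_folds: int = 5) -> tuple[int, ...]:
    """Geometric ladder 125, 250, 500, ... capped at the training pool."""
    cap = n - (n // n_folds) - 1
    sizes = []
    s = 125
    while s <= cap:
        sizes.append(s)
        s *= 2
    if not sizes:
        sizes = [max(cap, 2)]
    elif sizes[-1] < cap:
        sizes.append(cap)
    return tuple(sizes)


def cross_validate(dataset: LabeledDataset, plan: EvaluationPlan) -> pd.DataFrame:
    """Learning curves under k-fold cross-validation.

    Each fold serves once as the fixed-size test set; training sets of
    each requested size are subsampled (independently per size) from the
    remaining data.  Returns one row per (train_size, fold) with the MAE
    in label units and fit/predict wall times in seconds.
    """
    n = len(dataset)
    if n < plan.n_folds:
        raise ValueError("need at least n_folds structures")
    y_target = _targets_for_mode(dataset, plan.target_mode)
    feats = Features(dataset, plan.descriptor)
    perm = substream(plan.seed, "cv-folds").permutation(n)
    folds = np.array_split(perm, plan.n_folds)
    sizes = plan.train_sizes or default_train_sizes(n, plan.n_folds)
    pool_max = int(np.floor(n * (1 - 1 / plan.n_folds)))
    rows = []
    for fold_id, test_idx in enumerate(folds):
        rest = np.setdiff1d(perm, test_idx, assume_unique=True)
        for size in sizes:
            if size > pool_max:
                raise ValueError(
                    f"train_size {size} exceeds the {pool_max}-item training pool"
                )
            rng = substream(plan.seed, f"subsample-f{fold_id}-s{size}")
            train_idx = rng.choice(rest, size=size, replace=False)
            pred, fit_s, pred_s = fit_predict(
                plan.model, feats, y_target, train_idx, test_idx, seed=plan.seed
            )
            final = _final_prediction(dataset, plan.target_mode, test_idx, pred)
            rows.append(
                {
                    "model": plan.model.name,
                    "mode": plan.target_mode,
                    "train_size": size,
                    "fold": fold_id,
                    "mae": mae(dataset.y_high[test_idx], final),
                    "fit_s": fit_s,
                    "predict_s": pred_s,
                }
            )
    return pd.DataFrame(rows)


def extrapolation_split(
    dataset: LabeledDataset, holdout_composition: dict[str, int]
) -> tuple[LabeledDataset, LabeledDataset]:
    """Hold out every structure of one composition (e.g. the largest).

    Returns ``(train, test)``; raises when no structure matches, naming
    the composition.
    """
    is_test = np.array(
        [s.composition == holdout_composition for s in dataset.structures]
    )
    if not is_test.any():
        raise ValueError(
            f"no structure has composition {format_composition(holdout_composition)}"
        )
    return dataset.subset(np.where(~is_test)[0]), dataset.subset(np.where(is_test)[0])


def tune_krr_hyperparams(
    dataset: LabeledDataset,
    sigma_grid=None,
    lambda_grid=tuple(10.0 ** -np.arange(2, 11)),
    seed: int = 0,
    target_mode: str = "direct",
    descriptor: ManyBodyParams | None = None,
) -> tuple[float, float]:
    """Grid-search (sigma, lambda) on a seeded 4000/1000 train/validation split.

    Smaller datasets keep the 4:1 ratio.  Ties prefer the larger lambda,
    then the larger sigma (the more regularized model).
    """
    n = len(dataset)
    if n < 10:
        raise ValueError("need at least 10 structures to tune")
    y_target = _targets_for_mode(dataset, target_mode)
    feats = Features(dataset, descriptor)
    n_train = min(4000, (n * 4) // 5)
    n_val = min(1000, n - n_train)
    perm = substream(seed, "krr-tune-split").permutation(n)
    idx_train, idx_val = perm[:n_train], perm[n_train : n_train + n_val]
    reps_tr = [feats.local[i] for i in idx_train]
    reps_va = [feats.local[i] for i in idx_val]
    if sigma_grid is None:
        from molknn.kernels import sigma_grid as default_grid

        sigma_grid = default_grid(median_pairwise_distance(reps_tr))
    y_tr, y_va = y_target[idx_train], y_target[idx_val]
    best = None
    for sigma in sigma_grid:
        spec = KernelSpec(kind="extensive_atomic", sigma=float(sigma))
        K = kernel_matrix(reps_tr, reps_tr, spec)
        K_va = kernel_matrix(reps_va, reps_tr, spec)
        for lam in lambda_grid:
            fitted = krr_fit(K, y_tr, float(lam), spec=spec)
            score = mae(y_va, krr_predict(fitted, K_va))
            key = (score, -float(lam), -float(sigma))
            if best is None or key < best[0]:
                best = (key, float(sigma), float(lam))
    return best[1], best[2]


def tune_knn_k(
    dataset: LabeledDataset,
    model: ModelSpec,
    k_grid=tuple(range(1, 31)),
    seed: int = 0,
    target_mode: str = "direct",
    descriptor: ManyBodyParams | None = None,
    subsample_cap: int = 5000,
) -> int:
    """5-fold cross-validated choice of k on a seeded random subsample.

    The distance structure of each fold is computed once and reused for
    every k; ties prefer the smaller k.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    n = len(dataset)
    sub_n = min(subsample_cap, n)
    sub = substream(seed, "knn-tune-subsample").choice(n, size=sub_n, replace=False)
    ds = dataset.subset(np.sort(sub))
    y_target = _targets_for_mode(ds, target_mode)
    feats = Features(ds, descriptor)
    perm = substream(seed, "knn-tune-folds").permutation(sub_n)
    folds = np.array_split(perm, 5)
    kmax = max(k_grid)
    scores = {k: [] for k in k_grid}
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        if kmax > train_idx.size:
            raise ValueError("k_grid exceeds fold training size")
        dist, idx, y_tr = _neighbor_block(
            model, feats, y_target, train_idx, test_idx, seed, kmax
        )
        labels = y_tr[idx]
        for k in k_grid:
            from molknn.knn import _weighted_estimates

            est = _weighted_estimates(dist[:, :k], labels[:, :k], model.weighting)
            final = _final_prediction(ds, target_mode, test_idx, est)
            scores[k].append(mae(ds.y_high[test_idx], final))
    mean_scores = {k: float(np.mean(v)) for k, v in scores.items()}
    return min(k_grid, key=lambda k: (mean_scores[k], k))


def _neighbor_block(model, feats, y_target, idx_train, idx_test, seed, kmax):
    """Neighbour distances/indices of test vs train under the model's metric."""
    y_tr = np.asarray(y_target, dtype=float)[idx_train]
    if model.name == "knn_kernel_distance":
        sigma = _default_sigma(model, feats, idx_train)
        spec = KernelSpec(kind="extensive_atomic", sigma=sigma)
        reps_tr = [feats.local[i] for i in idx_train]
        reps_te = [feats.local[i] for i in idx_test]
        D = kernel_induced_distance(
            kernel_self_similarities(reps_te, spec),
            kernel_self_similarities(reps_tr, spec),
            kernel_matrix(reps_te, reps_tr, spec),
        )
        index = build_index(distances=np.zeros((len(idx_train),) * 2),
                            mode="kernel_induced")
        dist, idx = index.query(D, kmax)
        return dist, idx, y_tr
    G = feats.global_
    if model.name == "knn_mlkr":
        rank = min(model.rank_limit, G.shape[1])
        metric, _ = mlkr_fit(
            G[idx_train], y_tr, rank_limit=rank,
            subsample_cap=model.mlkr_subsample_cap, seed=seed,
            max_iter=model.mlkr_max_iter,
        )
        index = build_index(points=G[idx_train], mode="mahalanobis", metric=metric)
    else:
        index = build_index(points=G[idx_train], mode="euclidean")
    dist, idx = index.query(G[idx_test], kmax)
    return dist, idx, y_tr


def plot_learning_curves(results: pd.DataFrame, path) -> None:
    """Log-log learning-curve plot (mean MAE vs training size per model)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (model, mode), grp in results.groupby(["model", "mode"]):
        curve = grp.groupby("train_size")["mae"].mean()
        ax.loglog(curve.index, curve.values, marker="o", label=f"{model} ({mode})")
    ax.axhline(1.0, color="k", lw=1, label="chemical accuracy")
    ax.set_xlabel("training set size")
    ax.set_ylabel("test MAE (kcal/mol)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(percent_grid, observed, path) -> None:
    """Observed-vs-nominal percentile calibration plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 100], [0, 1], "r--", lw=1)
    ax.plot(list(percent_grid), list(observed), "bo")
    ax.set_xlabel("nominal percentile")
    ax.set_ylabel("observed fraction below")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
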