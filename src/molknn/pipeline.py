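"""Train/predict workflows and model serialization for the CLI.

A :class:`TrainedModel` bundles everything inference needs: the model
family and hyperparameters, the descriptor schema, the training
representations (global matrix or stacked local rows), the training
targets, and the fitted parameters (KRR dual weights or the learned
metric).  Models serialize to a single ``.npz`` archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from molknn.descriptors import LocalRepresentation, ManyBodyParams
from molknn.evaluate import Features, ModelSpec, _default_sigma, delta_targets
from molknn.kernels import (
    KernelSpec,
    kernel_induced_distance,
    kernel_matrix,
    kernel_self_similarities,
)
from molknn.knn import (
    build_index,
    knn_predict_batch,
    mlkr_kernel_regression_predict,
    neighbor_quantiles,
)
from molknn.krr import KRRModel, krr_fit, krr_predict
from molknn.mlkr import MahalanobisMetric, mlkr_fit
from molknn.structures import LabeledDataset

__all__ = ["TrainedModel", "train_model", "predict_table", "save_model", "load_model"]


@dataclass
class TrainedModel:
    spec: ModelSpec
    mode: str  # direct | delta
    descriptor: ManyBodyParams
    sigma: float  # resolved kernel width (KRR / kernel-distance models)
    y_train: np.ndarray  # target values (residuals in delta mode)
    global_train: np.ndarray | None = None
    local_train: list[LocalRepresentation] | None = None
    alpha: np.ndarray | None = None  # KRR dual weights
    metric: MahalanobisMetric | None = None
    train_ids: list[str] = field(default_factory=list)


def train_model(
    dataset: LabeledDataset, spec: ModelSpec, mode: str = "direct", seed: int = 0
) -> TrainedModel:
    """Fit one model family on a labelled dataset."""
    if mode not in ("direct", "delta"):
        raise ValueError("mode must be 'direct' or 'delta'")
    y = delta_targets(dataset) if mode == "delta" else dataset.y_high
    if y is None:
        raise ValueError("training requires labels")
    feats = Features(dataset)
    idx = np.arange(len(dataset))
    model = TrainedModel(
        spec=spec,
        mode=mode,
        descriptor=feats.params,
        sigma=float(_default_sigma(spec, feats, idx)),
        y_train=np.asarray(y, dtype=float),
        train_ids=[s.id for s in dataset.structures],
    )
    if spec.name in ("krr", "knn_kernel_distance"):
        model.local_train = feats.local
        if spec.name == "krr":
            kspec = KernelSpec(kind="extensive_atomic", sigma=model.sigma)
            K = kernel_matrix(feats.local, feats.local, kspec)
            model.alpha = krr_fit(K, model.y_train, spec.lambda_).alpha
    else:
        model.global_train = feats.global_
        if spec.name in ("knn_mlkr", "kernel_regression_mlkr"):
            rank = min(spec.rank_limit, model.global_train.shape[1])
            model.metric, _ = mlkr_fit(
                model.global_train,
                model.y_train,
                rank_limit=rank,
                subsample_cap=spec.mlkr_subsample_cap,
                seed=seed,
                max_iter=spec.mlkr_max_iter,
            )
    return model


def predict_table(
    model: TrainedModel,
    dataset: LabeledDataset,
    quantiles: tuple[float, ...] = (),
) -> pd.DataFrame:
    """Predict a dataset; one row per structure.

    Columns: id, estimate, then (k-NN models only) neighbour ids and
    distances and any requested label percentiles, estimated from the
    unweighted neighbour set.  Delta-mode models require low-level labels
    on the input and add them back into the estimate.
    """
    spec = model.spec
    if model.mode == "delta" and dataset.y_low is None:
        raise ValueError("delta-mode prediction requires low-level labels")
    params = replace(model.descriptor)
    feats = Features(dataset, params)
    ids = [s.id for s in dataset.structures]

    neighbors = None
    if spec.name == "krr":
        kspec = KernelSpec(kind="extensive_atomic", sigma=model.sigma)
        K_te = kernel_matrix(feats.local, model.local_train, kspec)
        est = krr_predict(
            KRRModel(alpha=model.alpha, lambda_=spec.lambda_, spec=kspec), K_te
        )
    elif spec.name == "knn_kernel_distance":
        kspec = KernelSpec(kind="extensive_atomic", sigma=model.sigma)
        D = kernel_induced_distance(
            kernel_self_similarities(feats.local, kspec),
            kernel_self_similarities(model.local_train, kspec),
            kernel_matrix(feats.local, model.local_train, kspec),
        )
        index = build_index(
            distances=np.zeros((len(model.y_train),) * 2), mode="kernel_induced"
        )
        est, dist, idx = knn_predict_batch(
            index, model.y_train, D, spec.k, spec.weighting, return_neighbors=True
        )
        neighbors = (dist, idx)
    elif spec.name == "knn_euclidean":
        index = build_index(points=model.global_train, backend=spec.backend)
        est, dist, idx = knn_predict_batch(
            index, model.y_train, feats.global_, spec.k, spec.weighting,
            return_neighbors=True,
        )
        neighbors = (dist, idx)
    elif spec.name == "knn_mlkr":
        index = build_index(
            points=model.global_train, mode="mahalanobis",
            backend=spec.backend, metric=model.metric,
        )
        est, dist, idx = knn_predict_batch(
            index, model.y_train, feats.global_, spec.k, spec.weighting,
            return_neighbors=True,
        )
        neighbors = (dist, idx)
    else:  # kernel_regression_mlkr
        est = mlkr_kernel_regression_predict(
            model.metric, model.global_train, model.y_train, feats.global_
        )

    if model.mode == "delta":
        est = dataset.y_low + est

    out = pd.DataFrame({"id": ids, "estimate": est})
    if neighbors is not None:
        dist, idx = neighbors
        out["neighbor_ids"] = [
            ";".join(model.train_ids[j] for j in row) for row in idx
        ]
        out["neighbor_distances"] = [
            ";".join(f"{d:.6g}" for d in row) for row in dist
        ]
        for p in quantiles:
            qvals = []
            for i, row in enumerate(idx):
                q = neighbor_quantiles(model.y_train[row], [p], method="weibull")[
                    float(p)
                ]
                if model.mode == "delta":
                    q = q + dataset.y_low[i]
                qvals.append(q)
            out[f"p{p:g}"] = qvals
    return out


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to one ``.npz`` archive."""
    meta = {
        "spec": model.spec.__dict__,
        "mode": model.mode,
        "sigma": model.sigma,
        "descriptor": {
            "cutoff": model.descriptor.cutoff,
            "n_radial": model.descriptor.n_radial,
            "radial_width": model.descriptor.radial_width,
            "n_angular": model.descriptor.n_angular,
            "element_set": list(model.descriptor.element_set),
        },
        "train_ids": model.train_ids,
    }
    arrays = {"y_train": model.y_train, "meta": np.array(json.dumps(meta))}
    if model.alpha is not None:
        arrays["alpha"] = model.alpha
    if model.metric is not None:
        arrays["metric_A"] = model.metric.A
        arrays["metric_sigma"] = np.array(model.metric.sigma)
    if model.global_train is not None:
        arrays["global_train"] = model.global_train
    if model.local_train is not None:
        arrays["local_stack"] = np.vstack([r.per_atom for r in model.local_train])
        arrays["local_counts"] = np.array([r.n_atoms for r in model.local_train])
        arrays["local_elements"] = np.array(
            [e for r in model.local_train for e in r.atom_elements]
        )
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        desc = meta["descriptor"]
        params = ManyBodyParams(
            cutoff=desc["cutoff"],
            n_radial=desc["n_radial"],
            radial_width=desc["radial_width"],
            n_angular=desc["n_angular"],
            element_set=tuple(desc["element_set"]),
        )
        model = TrainedModel(
            spec=ModelSpec(**meta["spec"]),
            mode=meta["mode"],
            descriptor=params,
            sigma=float(meta["sigma"]),
            y_train=z["y_train"],
            train_ids=list(meta["train_ids"]),
        )
        if "alpha" in z:
            model.alpha = z["alpha"]
        if "metric_A" in z:
            model.metric = MahalanobisMetric(
                A=z["metric_A"], sigma=float(z["metric_sigma"])
            )
        if "global_train" in z:
            model.global_train = z["global_train"]
        if "local_stack" in z:
            stack = z["local_stack"]
            counts = z["local_counts"]
            elements = [str(e) for e in z["local_elements"]]
            reps = []
            start = 0
            for c in counts:
                reps.append(
                    LocalRepresentation(
                        per_atom=stack[start : start + c],
                        atom_elements=elements[start : start + c],
                        feature_schema=params.schema(),
                    )
                )
                start += c
            model.local_train = reps
    return model
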