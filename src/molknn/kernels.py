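"""Kernels and the kernel-induced distance.

Two kernel families:

* ``global_rbf`` — the RBF kernel on global descriptor vectors,
  ``K_ij = exp(-||a_i - b_j||^2 / (2 sigma^2))``.
* ``extensive_atomic`` — a sum of pairwise atomic RBF kernels over local
  representations, by default restricted to same-element atom pairs.
  This kernel is *extensive*: the self-similarity of an n-atom structure
  grows with n, matching extensive target properties such as binding
  energies.

Any positive-definite kernel induces the feature-space distance
``d(x, x') = sqrt(k(x,x) + k(x',x') - 2 k(x,x'))`` used by the
kernel-distance k-NN variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from molknn.descriptors import GlobalRepresentation, LocalRepresentation

__all__ = [
    "KernelSpec",
    "kernel_matrix",
    "kernel_self_similarities",
    "kernel_induced_distance",
    "normalize_kernel",
    "median_pairwise_distance",
    "sigma_grid",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration: kind, RBF width sigma, element matching."""

    kind: str = "global_rbf"  # "global_rbf" | "extensive_atomic"
    sigma: float = 1.0
    element_matched: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("global_rbf", "extensive_atomic"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _sq_dists(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances via the BLAS-friendly identity."""
    d2 = (
        np.sum(Xa**2, axis=1)[:, None]
        + np.sum(Xb**2, axis=1)[None, :]
        - 2.0 * (Xa @ Xb.T)
    )
    return np.maximum(d2, 0.0, out=d2)


def _as_matrix(reps) -> np.ndarray:
    if isinstance(reps, np.ndarray):
        return np.atleast_2d(reps)
    return np.vstack(
        [r.vector if isinstance(r, GlobalRepresentation) else np.ravel(r) for r in reps]
    )


def _stack_local(reps: list[LocalRepresentation]):
    X = np.vstack([r.per_atom for r in reps])
    owner = np.concatenate(
        [np.full(r.n_atoms, i, dtype=int) for i, r in enumerate(reps)]
    )
    elements = np.array([e for r in reps for e in r.atom_elements])
    return X, owner, elements


def _check_schema(A, B) -> None:
    sa = getattr(A[0], "feature_schema", None) if not isinstance(A, np.ndarray) else None
    sb = getattr(B[0], "feature_schema", None) if not isinstance(B, np.ndarray) else None
    if sa and sb and sa != sb:
        raise ValueError("representation schemas differ between A and B")


def kernel_matrix(A, B, spec: KernelSpec, block_size: int = 1024) -> np.ndarray:
    """Dense kernel matrix between two representation collections.

    ``global_rbf`` expects arrays / GlobalRepresentation lists; the
    extensive kernel expects LocalRepresentation lists and evaluates
    ``K_ij = sum_{alpha in i} sum_{beta in j} [Z match] rbf(q_alpha, q_beta)``.
    Atom blocks of ``block_size`` rows bound peak memory; results are
    independent of the block size.
    """
    _check_schema(A, B)
    s2 = 2.0 * spec.sigma**2
    if spec.kind == "global_rbf":
        Xa, Xb = _as_matrix(A), _as_matrix(B)
        if Xa.shape[1] != Xb.shape[1]:
            raise ValueError("representation dimensions differ")
        G = _sq_dists(Xa, Xb)
        G /= -s2
        return np.exp(G, out=G)

    Xa, owner_a, el_a = _stack_local(list(A))
    Xb, owner_b, el_b = _stack_local(list(B))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("representation dimensions differ")
    K = np.zeros((len(A), len(B)))
    if spec.element_matched:
        groups = [
            (np.where(el_a == e)[0], np.where(el_b == e)[0])
            for e in np.unique(el_a)
        ]
    else:
        groups = [(np.arange(len(el_a)), np.arange(len(el_b)))]
    for ia, ib in groups:
        if ia.size == 0 or ib.size == 0:
            continue
        # atoms are stored grouped by structure, so owners are sorted
        # within an element group and segment sums (reduceat) apply
        ua, starts_a = np.unique(owner_a[ia], return_index=True)
        ub, starts_b = np.unique(owner_b[ib], return_index=True)
        xb = Xb[ib]
        acc = np.zeros((ua.size, ub.size))
        for start in range(0, ia.size, block_size):
            blk = ia[start : start + block_size]
            G = _sq_dists(Xa[blk], xb)
            G /= -s2
            np.exp(G, out=G)
            cols = np.add.reduceat(G, starts_b, axis=1)
            seg = np.searchsorted(ua, owner_a[blk])
            seg_rows, first = np.unique(seg, return_index=True)
            acc[seg_rows] += np.add.reduceat(cols, first, axis=0)
        K[np.ix_(ua, ub)] += acc
    return K


def kernel_self_similarities(A, spec: KernelSpec) -> np.ndarray:
    """Vector of self-similarities ``k(x_i, x_i)`` for each structure."""
    if spec.kind == "global_rbf":
        return np.ones(len(_as_matrix(A)))
    out = np.empty(len(A))
    for i, rep in enumerate(A):
        out[i] = kernel_matrix([rep], [rep], spec)[0, 0]
    return out


def kernel_induced_distance(
    K_aa_diag: np.ndarray,
    K_bb_diag: np.ndarray,
    K_ab: np.ndarray,
    rel_tol: float = 1e-9,
) -> np.ndarray:
    """Feature-space distance from kernel evaluations.

    ``D_ij = sqrt(k(x_i,x_i) + k(x_j,x_j) - 2 k(x_i,x_j))``.  Tiny negative
    arguments under the root (relative magnitude <= ``rel_tol``) are
    clamped to zero; stronger negativity signals a non-positive-definite
    kernel and raises.
    """
    ka = np.asarray(K_aa_diag, dtype=float).ravel()
    kb = np.asarray(K_bb_diag, dtype=float).ravel()
    K_ab = np.asarray(K_ab, dtype=float)
    if K_ab.shape != (ka.size, kb.size):
        raise ValueError("cross-kernel shape does not match the diagonals")
    arg = ka[:, None] + kb[None, :] - 2.0 * K_ab
    scale = np.maximum(ka[:, None] + kb[None, :], 1.0)
    if np.any(arg < -rel_tol * scale):
        raise ValueError(
            "strongly negative squared distance: kernel is not positive definite"
        )
    return np.sqrt(np.maximum(arg, 0.0))


def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Cosine-normalize a square kernel so the diagonal is exactly 1."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("normalize_kernel expects a square matrix")
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("kernel diagonal must be strictly positive")
    s = np.sqrt(d)
    return K / np.outer(s, s)


def median_pairwise_distance(X, rng=None, max_points: int = 2000) -> float:
    """Median pairwise Euclidean distance (subsampled above ``max_points``).

    For local representations the atomic environment rows are pooled.
    The result anchors the sigma grid search.
    """
    if not isinstance(X, np.ndarray):
        first = X[0] if len(X) else None
        if isinstance(first, LocalRepresentation):
            X = np.vstack([r.per_atom for r in X])
        else:
            X = _as_matrix(X)
    n = X.shape[0]
    if n > max_points:
        rng = np.random.default_rng(0) if rng is None else rng
        X = X[rng.choice(n, size=max_points, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def sigma_grid(reference_distance: float) -> list[float]:
    """Default sigma grid: decades of the median pairwise distance."""
    return [f * reference_distance for f in (0.5, 1, 2, 5, 10, 20, 50)]
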