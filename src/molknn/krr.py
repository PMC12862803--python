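"""Kernel ridge regression: closed-form solve and prediction.

The model is ``f(x) = sum_i alpha_i k(x_i, x)`` with weights solved from
``(K + lambda I) alpha = y`` by a symmetric positive-definite (Cholesky)
factorization; one retry adds a trace-scaled jitter before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from molknn.kernels import KernelSpec

__all__ = ["KRRModel", "krr_fit", "krr_predict"]


@dataclass
class KRRModel:
    alpha: np.ndarray
    lambda_: float
    spec: KernelSpec | None = None
    train_reps: object = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return len(self.alpha)


def krr_fit(
    K: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    spec: KernelSpec | None = None,
    train_reps=None,
) -> KRRModel:
    """Solve ``(K + lambda I) alpha = y``.

    Raises a numerical error advising ``lambda_ > 0`` when the
    factorization fails even after a small jitter retry, and verifies the
    residual ``||(K + lambda I) alpha - y|| <= 1e-8 ||y||``.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = K.shape[0]
    if K.shape != (n, n) or y.size != n:
        raise ValueError("K must be square and match len(y)")
    if lambda_ < 0:
        raise ValueError("lambda_ must be non-negative")
    M = K + lambda_ * np.eye(n)
    try:
        c = cho_factor(M, lower=True)
    except LinAlgError:
        jitter = 1e-10 * np.trace(K) / n
        try:
            c = cho_factor(M + jitter * np.eye(n), lower=True)
        except LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "kernel matrix factorization failed; use lambda_ > 0 for a "
                "singular or ill-conditioned kernel"
            ) from exc
    alpha = cho_solve(c, y)
    # iterative refinement: ill-conditioned extensive kernels leave a
    # noticeable first-pass residual that a few correction solves remove
    tol = 1e-8 * max(np.linalg.norm(y), 1e-300)
    for _ in range(12):
        r = y - M @ alpha
        if np.linalg.norm(r) <= tol:
            break
        alpha = alpha + cho_solve(c, r)
    resid = np.linalg.norm(M @ alpha - y)
    if resid > tol:
        raise np.linalg.LinAlgError(
            f"solve residual {resid:.3e} too large; use lambda_ > 0"
        )
    return KRRModel(alpha=alpha, lambda_=float(lambda_), spec=spec,
                    train_reps=train_reps)


def krr_predict(model: KRRModel, K_test: np.ndarray) -> np.ndarray:
    """Predict ``f_i = sum_j alpha_j K_test[i, j]`` for test-train kernels."""
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    if K_test.shape[1] != model.n_train:
        raise ValueError(
            f"K_test has {K_test.shape[1]} columns, expected {model.n_train}"
        )
    return K_test @ model.alpha
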