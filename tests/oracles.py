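"""Independent brute-force oracles for the trilinear machinery.

Deliberately naive: everything is materialized through explicit Kronecker /
Khatri-Rao design matrices and `numpy.linalg.lstsq`, sharing no code with
the package's fitting path.  Only usable at toy sizes.
"""

from __future__ import annotations

import numpy as np


def khatri_rao(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product, rows indexed (p, q) with p outer."""
    F = P.shape[1]
    return np.stack([np.kron(P[:, f], Q[:, f]) for f in range(F)], axis=1)


def brute_force_als(
    X: np.ndarray, F: int, n_iter: int = 2000, seed: int = 0, tol: float = 1e-14
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Unconstrained trilinear least squares by explicit lstsq per mode.

    Returns (A, B, C, sse).  Every mode update solves the full linear
    system `unfolding ~ M @ khatri_rao(other1, other2).T` via lstsq on the
    materialized Khatri-Rao matrix.
    """
    I, J, K = X.shape
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((I, F))
    B = rng.standard_normal((J, F))
    C = rng.standard_normal((K, F))
    X0 = X.reshape(I, J * K)
    X1 = np.moveaxis(X, 1, 0).reshape(J, I * K)
    X2 = np.moveaxis(X, 2, 0).reshape(K, I * J)
    prev = np.inf
    for _ in range(n_iter):
        A = np.linalg.lstsq(khatri_rao(B, C), X0.T, rcond=None)[0].T
        B = np.linalg.lstsq(khatri_rao(A, C), X1.T, rcond=None)[0].T
        C = np.linalg.lstsq(khatri_rao(A, B), X2.T, rcond=None)[0].T
        sse = float(np.sum((X0 - A @ khatri_rao(B, C).T) ** 2))
        if prev - sse < tol * max(prev, 1e-300):
            break
        prev = sse
    return A, B, C, sse


def tucker_core_lstsq(
    X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Least-squares Tucker3 core via one explicit Kronecker lstsq solve."""
    F = A.shape[1]
    design = np.kron(np.kron(A, B), C)  # (I*J*K) x F^3, vec with i outer
    g, *_ = np.linalg.lstsq(design, X.ravel(), rcond=None)
    return g.reshape(F, F, F)


def corcondia_oracle(X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray) -> float:
    """Core consistency from the brute-force Tucker core."""
    F = A.shape[1]
    G = tucker_core_lstsq(X, A, B, C)
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / F)


def nnls_reference(G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Reference NNLS for one row via scipy on a Cholesky square root."""
    from scipy.optimize import nnls as scipy_nnls

    L = np.linalg.cholesky(G + 1e-13 * np.trace(G) / G.shape[0] * np.eye(G.shape[0]))
    x, _ = scipy_nnls(L.T, np.linalg.solve(L, w))
    return x


def unimodal_brute_force(y: np.ndarray) -> np.ndarray:
    """Exact unimodal non-negative fit by trying every peak split with PAVA
    done through scipy's isotonic solver."""
    from scipy.optimize import isotonic_regression

    n = y.size
    best, best_sse = None, np.inf
    for k in range(n):
        left = isotonic_regression(y[: k + 1], increasing=True).x
        right = isotonic_regression(y[k + 1 :], increasing=False).x if k + 1 < n else np.empty(0)
        fit = np.clip(np.concatenate([left, right]), 0.0, None)
        sse = float(np.sum((fit - y) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = fit, sse
    return best
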