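"""Exact batched non-negative least squares on a shared Gram matrix.

The alternating least squares mode updates in constrained PARAFAC solve,
for every row x of a loading matrix,

    min_{x >= 0}  (1/2) x' G x - w' x,

where the F x F Gram matrix G is shared by all rows and only the linear
term w differs.  For the small F used in EEM work (F <= ~10) the exact
solution is found by enumerating passive sets: for each subset S of
variables solve the unconstrained system on S, then keep the candidate
satisfying the Karush-Kuhn-Tucker conditions.  Each subset's solve is
vectorized across all rows at once, which is what makes constrained ALS
fast enough for dense EEM cubes.  Clipping is never used, so the ALS loss
is guaranteed non-increasing.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["nnls_gram_batch"]

_ENUM_MAX_F = 10


def _scipy_fallback(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-by-row Lawson-Hanson NNLS via a Cholesky square root of G."""
    F = G.shape[0]
    ridge = 1e-12 * max(np.trace(G) / F, 1.0)
    L = np.linalg.cholesky(G + ridge * np.eye(F))
    out = np.empty_like(W)
    for i, w in enumerate(W):
        b = np.linalg.solve(L, w)  # min ||L' x - b||  <=>  min x'Gx/2 - w'x
        out[i], _ = _scipy_nnls(L.T, b)
    return out


def nnls_gram_batch(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve min_{x>=0} (1/2) x'Gx - w'x for every row w of W.

    Parameters
    ----------
    G : (F, F) symmetric positive semi-definite Gram matrix.
    W : (n, F) linear terms, one row per problem.

    Returns
    -------
    (n, F) array of exact non-negative minimizers.
    """
    G = np.asarray(G, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n, F = W.shape
    if G.shape != (F, F):
        raise ValueError(f"Gram shape {G.shape} does not match W columns {F}")
    if F > _ENUM_MAX_F:
        return _scipy_fallback(G, W)

    scale = max(float(np.abs(G).max()), 1e-300)
    wscale = np.maximum(np.abs(W).max(axis=1), 1e-300)
    x_tol = 1e-10
    g_tol = 1e-8

    best_x = np.zeros((n, F))
    best_obj = np.zeros(n)  # objective of x = 0
    # x = 0 is KKT-feasible iff all gradients -w are >= 0
    feasible = np.all(W <= g_tol * wscale[:, None], axis=1)
    best_obj[~feasible] = np.inf

    idx = np.arange(F)
    for size in range(1, F + 1):
        for S in combinations(idx, size):
            S = np.array(S)
            GSS = G[np.ix_(S, S)]
            try:
                c, low = cho_factor(GSS + 1e-14 * scale * np.eye(size))
                Z = cho_solve((c, low), W[:, S].T).T  # (n, |S|)
            except np.linalg.LinAlgError:
                Z, *_ = np.linalg.lstsq(GSS, W[:, S].T, rcond=None)
                Z = Z.T
            ok = np.all(Z >= -x_tol * wscale[:, None] / scale, axis=1)
            if not np.any(ok):
                continue
            # gradient on the active (zeroed) set must be non-negative
            notS = np.setdiff1d(idx, S, assume_unique=True)
            if notS.size:
                grad = Z @ G[np.ix_(S, notS)] - W[:, notS]
                ok &= np.all(grad >= -g_tol * wscale[:, None], axis=1)
            if not np.any(ok):
                continue
            obj = 0.5 * np.einsum("ij,ij->i", Z @ GSS, Z) - np.einsum(
                "ij,ij->i", Z, W[:, S]
            )
            better = ok & (obj < best_obj - 1e-15)
            if np.any(better):
                best_obj[better] = obj[better]
                best_x[np.ix_(better, S)] = np.maximum(Z[better], 0.0)
                best_x[np.ix_(better, notS)] = 0.0

    # numerical safety net: any row never matched by an enumerated KKT point
    bad = ~np.isfinite(best_obj)
    if np.any(bad):
        best_x[bad] = _scipy_fallback(G, W[bad])
    return best_x
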