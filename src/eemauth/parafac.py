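"""Constrained PARAFAC for EEM cubes, with model-selection diagnostics.

The trilinear model approximates the cube X (samples x excitation x
emission) as

    X[i,j,k] = sum_f A[i,f] * B[j,f] * C[k,f] + e[i,j,k],

fitted by alternating least squares (ALS) minimizing the sum of squared
residuals.  Non-negativity is enforced by exact non-negative least squares
per mode (never clipping), so the loss is non-increasing at every
iteration; unimodality on the spectral modes is available via unimodal
regression.  Model order is chosen by scanning component counts and
comparing explained variance, the core consistency diagnostic (CORCONDIA),
and split-half similarity of the spectral loadings, exploiting the
uniqueness of the trilinear decomposition.  Fitted components are assigned
to the fluorophore classes expected in virgin olive oil from the position
of their excitation/emission maxima.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from eemauth._nnls import nnls_gram_batch
from eemauth._unimodal import unimodal_nonneg_regression
from eemauth.eem_io import EEMCube, EEMError

__all__ = [
    "ParafacModel",
    "ModelSelectionReport",
    "FluorophoreAssignment",
    "DEFAULT_FLUOROPHORE_RULES",
    "init_svd",
    "fit_parafac",
    "explained_variance",
    "core_consistency",
    "congruence",
    "match_components",
    "split_half",
    "scan_components",
    "identify_fluorophores",
]

log = logging.getLogger(__name__)

NONNEGATIVITY = "nonnegativity"
UNIMODALITY = "unimodality"


@dataclass
class ParafacModel:
    """A fitted trilinear decomposition.

    Columns of B (excitation) and C (emission) have unit Euclidean norm;
    component magnitude is carried by A (mode-1 relative concentrations).
    Components are ordered by descending column norm of A.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    F: int
    sse: float
    explained_pct: float
    n_iter: int
    converged: bool
    constraints: frozenset[str]
    ex_values: np.ndarray
    em_values: np.ndarray
    loss_history: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def reconstruct(self) -> np.ndarray:
        """Model cube X_hat[i,j,k] = sum_f A[i,f] B[j,f] C[k,f]."""
        return np.einsum("if,jf,kf->ijk", self.A, self.B, self.C)


@dataclass
class ModelSelectionRow:
    F: int
    core_consistency_pct: float
    explained_pct: float
    residual: float
    residual_scaled: float
    split_half_pct: float


@dataclass
class ModelSelectionReport:
    """Per-component-count diagnostics; residuals scaled to their maximum."""

    rows: list[ModelSelectionRow]

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "F": r.F,
                    "core_consistency_pct": r.core_consistency_pct,
                    "explained_pct": r.explained_pct,
                    "residual_scaled": r.residual_scaled,
                    "split_half_pct": r.split_half_pct,
                }
                for r in self.rows
            ]
        }


@dataclass
class FluorophoreAssignment:
    component: int
    name: str  # chlorophyll | oxidation | tocopherol | phenolic | unassigned
    peak_ex: float
    peak_em: float


def _unfoldings(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    I, J, K = X.shape
    X0 = X.reshape(I, J * K)                     # rows: samples
    X1 = np.moveaxis(X, 1, 0).reshape(J, I * K)  # rows: excitation
    X2 = np.moveaxis(X, 2, 0).reshape(K, I * J)  # rows: emission
    return X0, X1, X2


def _clip_small_positive(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    for f in range(out.shape[1]):
        col = out[:, f]
        if -col.min() > col.max():  # mostly negative: flip sign
            col = -col
        floor = 1e-6 * max(col.max(), 1e-30)
        out[:, f] = np.maximum(col, floor)
    return out


def init_svd(
    cube: EEMCube, F: int, seed: int = 0, replicate: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mode-wise SVD initialization for ALS.

    Leading left singular vectors of each unfolding, sign-corrected and
    clipped to small positive values so non-negative ALS starts feasibly.
    Replicates 2-3 perturb the SVD start; replicates >= 4 use seeded
    random starts, since perturbations of one start tend to fall back
    into its basin of attraction.
    """
    if F < 1:
        raise EEMError("F must be >= 1")
    shapes = [Xn.shape[0] for Xn in _unfoldings(cube.data)]
    if replicate >= 4:
        rng = np.random.default_rng([seed, replicate])
        mats = [rng.uniform(0.1, 1.0, size=(n, F)) for n in shapes]
        return mats[0], mats[1], mats[2]
    mats = []
    rng = np.random.default_rng(seed)
    for Xn in _unfoldings(cube.data):
        n = Xn.shape[0]
        rank = np.linalg.matrix_rank(Xn) if min(Xn.shape) <= 64 else min(Xn.shape)
        if F > min(n, rank):
            log.info("init_svd: F=%d exceeds unfolding rank %d; random init", F, rank)
            mats.append(rng.uniform(0.1, 1.0, size=(n, F)))
            continue
        U, _, _ = np.linalg.svd(Xn, full_matrices=False)
        mats.append(_clip_small_positive(U[:, :F]))
    if replicate >= 2:
        rng = np.random.default_rng([seed, replicate])
        mats = [M * (1.0 + 0.3 * rng.uniform(-1.0, 1.0, size=M.shape)) for M in mats]
        mats = [np.abs(M) for M in mats]
    return mats[0], mats[1], mats[2]


def _update_mode(
    Xn: np.ndarray,
    others: tuple[np.ndarray, np.ndarray],
    current: np.ndarray,
    nonneg: bool,
    unimodal: bool,
) -> np.ndarray:
    """One ALS update of a mode's loading matrix.

    ``others`` are the two fixed loading matrices (P, Q) such that the
    unfolding satisfies Xn ~ M @ khatri_rao(P, Q).T with M the mode being
    updated.  Gram products are formed as Hadamard products of the small
    F x F cross-products, never materializing the Khatri-Rao matrix.
    """
    P, Q = others
    G = (P.T @ P) * (Q.T @ Q)                      # F x F
    # W = Xn @ khatri_rao(P, Q), computed as a contraction
    n = Xn.shape[0]
    W = np.einsum(
        "npq,pf,qf->nf", Xn.reshape(n, P.shape[0], Q.shape[0]), P, Q, optimize=True
    )
    if unimodal:
        M = current.copy()
        diag = np.diag(G).copy()
        diag[diag <= 0] = 1e-30
        for f in range(M.shape[1]):
            target = (W[:, f] - M @ G[:, f] + M[:, f] * G[f, f]) / diag[f]
            M[:, f] = unimodal_nonneg_regression(target)
        return M
    if nonneg:
        return nnls_gram_batch(G, W)
    ridge = 1e-12 * max(np.trace(G) / G.shape[0], 1e-30)
    return np.linalg.solve(G + ridge * np.eye(G.shape[0]), W.T).T


def _loss(ssx: float, A: np.ndarray, B: np.ndarray, C: np.ndarray, WC: np.ndarray) -> float:
    """SSE via ||X||^2 - 2<X, Xhat> + ||Xhat||^2 without reconstruction.

    WC must be the mode-3 linear term X(3) @ khatri_rao(A, B) for the
    *current* A, B; C the current mode-3 loadings.
    """
    had = float(np.sum((A.T @ A) * (B.T @ B) * (C.T @ C)))
    inner = float(np.sum(WC * C))
    return max(ssx - 2.0 * inner + had, 0.0)


def _normalize_model(A: np.ndarray, B: np.ndarray, C: np.ndarray):
    """Unit-norm B, C columns; magnitude into A; order by descending ||A_f||."""
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    B = B / nb
    C = C / nc
    A = A * (nb * nc)
    # sign convention (moot under non-negativity): largest |entry| positive
    for M in (B, C):
        for f in range(M.shape[1]):
            j = np.argmax(np.abs(M[:, f]))
            if M[j, f] < 0:
                M[:, f] = -M[:, f]
                A[:, f] = -A[:, f]
    order = np.argsort(-np.linalg.norm(A, axis=0), kind="stable")
    return A[:, order], B[:, order], C[:, order]


def _fit_single(
    X: np.ndarray,
    F: int,
    nonneg: bool,
    unimodal: bool,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
    deadline: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    X0, X1, X2 = _unfoldings(X)
    ssx = float(np.sum(X * X))
    prev = np.inf
    losses = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _update_mode(X0, (B, C), A, nonneg, False)  # mode 1 never unimodal
        B = _update_mode(X1, (A, C), B, nonneg, unimodal)
        C = _update_mode(X2, (A, B), C, nonneg, unimodal)
        WC = np.einsum("kij,if,jf->kf", X2.reshape(X.shape[2], X.shape[0], X.shape[1]),
                       A, B, optimize=True)
        cur = _loss(ssx, A, B, C, WC)
        losses.append(cur)
        if cur > prev * (1.0 + 1e-9) + 1e-12 * ssx:
            raise RuntimeError(
                f"ALS loss increased at iteration {it}: {prev!r} -> {cur!r}"
            )
        if np.isfinite(prev) and prev - cur <= tol * max(prev, 1e-300):
            converged = True
            break
        prev = cur
        if time.monotonic() > deadline:
            break
    return A, B, C, (losses[-1] if losses else ssx), it, converged, np.array(losses)


def fit_parafac(
    cube: EEMCube,
    F: int,
    constraints: frozenset[str] | set[str] | tuple[str, ...] = (NONNEGATIVITY,),
    tol: float = 1e-10,
    max_time: float = 300.0,
    replicates: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
) -> ParafacModel:
    """Fit a PARAFAC model by multi-start constrained ALS; keep the best.

    Parameters
    ----------
    cube : preprocessed EEM cube (scatter already zeroed).
    F : number of trilinear components.
    constraints : subset of {"nonnegativity", "unimodality"}; unimodality
        applies to the spectral modes (excitation and emission) only.
    tol : relative SSE-change convergence threshold.
    max_time : wall-clock budget (s) shared by all replicates.
    replicates : number of differently initialized ALS starts; the first
        uses the plain SVD start, later ones perturb it.
    """
    if F < 1:
        raise EEMError("F must be >= 1")
    if replicates < 1:
        raise EEMError("replicates must be >= 1")
    X = cube.data
    ssx = float(np.sum(X * X))
    if ssx == 0.0:
        raise EEMError("cannot fit PARAFAC to an all-zero cube")
    constraints = frozenset(constraints)
    unknown = constraints - {NONNEGATIVITY, UNIMODALITY}
    if unknown:
        raise EEMError(f"unknown constraints: {sorted(unknown)}")
    nonneg = NONNEGATIVITY in constraints
    unimodal = UNIMODALITY in constraints

    deadline = time.monotonic() + max_time
    best = None
    for rep in range(1, replicates + 1):
        A0, B0, C0 = init_svd(cube, F, seed=seed, replicate=rep)
        A, B, C, sse, n_iter, conv, losses = _fit_single(
            X, F, nonneg, unimodal, A0, B0, C0, tol, max_iter, deadline
        )
        if best is None or sse < best[3]:
            best = (A, B, C, sse, n_iter, conv, losses)
        if time.monotonic() > deadline:
            if rep < replicates:
                log.warning("fit_parafac: time budget reached after replicate %d", rep)
            break

    A, B, C, sse, n_iter, conv, losses = best
    if not conv:
        log.warning("fit_parafac: best replicate did not converge (F=%d)", F)
    A, B, C = _normalize_model(A, B, C)
    # degeneracy diagnostic: strongly negatively correlated component pair
    for f in range(F):
        for g in range(f + 1, F):
            cong = (
                congruence(A[:, f], A[:, g])
                * congruence(B[:, f], B[:, g])
                * congruence(C[:, f], C[:, g])
            )
            if cong < -0.85:
                log.warning(
                    "fit_parafac: degenerate pair (%d, %d), triple congruence %.3f",
                    f, g, cong,
                )
    return ParafacModel(
        A=A, B=B, C=C, F=F, sse=float(sse),
        explained_pct=100.0 * (1.0 - sse / ssx),
        n_iter=n_iter, converged=bool(conv), constraints=constraints,
        ex_values=cube.ex.values.copy(), em_values=cube.em.values.copy(),
        loss_history=losses,
    )


def explained_variance(model: ParafacModel, cube: EEMCube) -> float:
    """100 * (1 - SSE / SSX), SSX over the uncentered cube."""
    ssx = float(np.sum(cube.data**2))
    if ssx == 0.0:
        raise EEMError("explained variance undefined for an all-zero cube")
    resid = cube.data - model.reconstruct()
    return 100.0 * (1.0 - float(np.sum(resid**2)) / ssx)


def core_consistency(model: ParafacModel, cube: EEMCube) -> float:
    """Core consistency diagnostic (CORCONDIA), in percent.

    Computes the least-squares Tucker3 core G for the model's loadings and
    compares it to the F x F x F superidentity T:
    100 * (1 - sum((G - T)^2) / sum(T^2)).  Values near 100 indicate an
    appropriate trilinear model; large deviations (possibly negative)
    indicate redundant components.  The least-squares core under the
    Kronecker-structured design factorizes into mode-wise pseudo-inverses.
    """
    Ap, Bp, Cp = (np.linalg.pinv(M) for M in (model.A, model.B, model.C))
    G = np.einsum("fi,gj,hk,ijk->fgh", Ap, Bp, Cp, cube.data, optimize=True)
    F = model.F
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / F)


def congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) of two vectors."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_components(
    B1: np.ndarray, C1: np.ndarray, B2: np.ndarray, C2: np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy matching of components across two fits.

    Pairs are chosen by descending product of spectral congruences
    (B and C); ties broken by component index.  Returns a list of
    (index in fit 1, index in fit 2, congruence product).
    """
    F = B1.shape[1]
    scores = np.empty((F, F))
    for f in range(F):
        for g in range(F):
            scores[f, g] = congruence(B1[:, f], B2[:, g]) * congruence(C1[:, f], C2[:, g])
    pairs = []
    used1: set[int] = set()
    used2: set[int] = set()
    order = sorted(
        ((f, g) for f in range(F) for g in range(F)),
        key=lambda fg: (-scores[fg], fg),
    )
    for f, g in order:
        if f in used1 or g in used2:
            continue
        pairs.append((f, g, float(scores[f, g])))
        used1.add(f)
        used2.add(g)
        if len(pairs) == F:
            break
    return pairs


def _alternating_halves(cube: EEMCube) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint halves by alternating index, stratified by class label."""
    I = cube.n_samples
    h1: list[int] = []
    h2: list[int] = []
    if cube.labels is not None:
        for lab in dict.fromkeys(cube.labels):  # preserve label order
            idx = [i for i in range(I) if cube.labels[i] == lab]
            h1.extend(idx[0::2])
            h2.extend(idx[1::2])
        h1.sort()
        h2.sort()
    else:
        h1 = list(range(0, I, 2))
        h2 = list(range(1, I, 2))
    return np.array(h1), np.array(h2)


def split_half(
    cube: EEMCube,
    F: int,
    scheme: str = "alternating",
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Split-half similarity of the spectral loadings, in percent.

    The samples are split into two disjoint halves (alternating index,
    stratified by class label when labels exist), PARAFAC is fitted
    independently on each, components are greedily matched by Tucker
    congruence, and the similarity is 100 x the mean over matched
    components of the product of B- and C-loading congruences.  Near 100
    means both halves found the same spectra — the fingerprint of a valid
    trilinear model.
    """
    if cube.n_samples < 4:
        raise EEMError("split-half validation requires at least 4 samples")
    if scheme == "alternating":
        idx1, idx2 = _alternating_halves(cube)
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(cube.n_samples)
        idx1, idx2 = np.sort(perm[0::2]), np.sort(perm[1::2])
    else:
        raise EEMError(f"unknown split scheme {scheme!r}")
    m1 = fit_parafac(cube.subset(idx1), F, seed=seed, **fit_kwargs)
    m2 = fit_parafac(cube.subset(idx2), F, seed=seed + 1, **fit_kwargs)
    pairs = match_components(m1.B, m1.C, m2.B, m2.C)
    sims = [max(p[2], 0.0) for p in pairs]
    return 100.0 * float(np.mean(sims))


def scan_components(
    cube: EEMCube,
    F_max: int,
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelectionReport:
    """Fit models with F = 1..F_max and tabulate selection diagnostics.

    Each row carries explained variance, core consistency, split-half
    similarity and the residual sum of squares scaled to the largest
    residual across rows (so the F = 1 row reads 1.0 when it is worst).
    """
    if F_max < 1:
        raise EEMError("F_max must be >= 1")
    rows = []
    for F in range(1, F_max + 1):
        model = fit_parafac(cube, F, seed=seed, **fit_kwargs)
        cc = core_consistency(model, cube)
        sh = split_half(cube, F, seed=seed, **fit_kwargs)
        rows.append(
            ModelSelectionRow(
                F=F,
                core_consistency_pct=cc,
                explained_pct=model.explained_pct,
                residual=model.sse,
                residual_scaled=np.nan,
                split_half_pct=sh,
            )
        )
    max_resid = max(r.residual for r in rows)
    for r in rows:
        r.residual_scaled = r.residual / max_resid if max_resid > 0 else 0.0
    return ModelSelectionReport(rows=rows)


#: Ordered identification rules: (name, ex window or None, em window or None).
#: A component is assigned to the first rule whose windows contain its
#: excitation/emission argmax peaks.
DEFAULT_FLUOROPHORE_RULES: list[tuple[str, tuple[float, float] | None, tuple[float, float] | None]] = [
    ("chlorophyll", None, (650.0, 700.0)),
    ("oxidation", (310.0, 360.0), (500.0, 560.0)),
    ("tocopherol", (285.0, 300.0), (380.0, 470.0)),
    ("phenolic", (265.0, 285.0), (295.0, 380.0)),
]


def identify_fluorophores(
    model: ParafacModel,
    rules: list[tuple[str, tuple[float, float] | None, tuple[float, float] | None]] | None = None,
) -> list[FluorophoreAssignment]:
    """Assign each component to a fluorophore class from its peak positions.

    Peaks are the wavelengths of the argmax of each B (excitation) and C
    (emission) loading column.  Default windows reflect the landscapes of
    the four dominant virgin-olive-oil fluorophores: chlorophylls
    (em 650-700 nm), oxidation products (ex 310-360, em 500-560 nm),
    tocopherols (ex 285-300, em 380-470 nm) and phenolics (ex 265-285,
    em 295-380 nm).  Components matching no rule are ``unassigned``.
    """
    if rules is None:
        rules = DEFAULT_FLUOROPHORE_RULES
    out = []
    for f in range(model.F):
        pex = float(model.ex_values[int(np.argmax(model.B[:, f]))])
        pem = float(model.em_values[int(np.argmax(model.C[:, f]))])
        name = "unassigned"
        for rule_name, ex_win, em_win in rules:
            if ex_win is not None and not (ex_win[0] <= pex <= ex_win[1]):
                continue
            if em_win is not None and not (em_win[0] <= pem <= em_win[1]):
                continue
            name = rule_name
            break
        out.append(FluorophoreAssignment(component=f, name=name, peak_ex=pex, peak_em=pem))
    return out
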