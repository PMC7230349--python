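"""Discriminant tri-linear PLS (tri-PLS1 / DN-PLSR) on EEM cubes.

Each latent variable (LV) decomposes the three-way array into a triad:
one score vector t over samples and two unit-norm weight vectors, wJ over
excitation and wK over emission,

    X[i,j,k] ~ t[i] * wJ[j] * wK[k],

with (wJ, wK) chosen to maximize the covariance of t with the response —
they are the leading singular pair of the J x K matrix formed by weighting
each sample's landscape by its current response residual and summing over
samples.  The response y is the 0/1 class coding of sample origin.  After
each LV the cube is deflated by projecting out the score, which keeps
successive scores mutually orthogonal, and the inner regression of y on
all scores so far gives the prediction.  Model complexity is selected by
venetian-blinds cross-validation (fold = sample index mod s) using
calibration/validation RMSE and classification accuracy; variable
importance in projection (VIP) maps localize the discriminating
excitation/emission regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eemauth.eem_io import EEMCube, EEMError

__all__ = [
    "NPLSModel",
    "CVResult",
    "VIPMap",
    "encode_response",
    "fit_npls",
    "predict",
    "venetian_blinds_folds",
    "cross_validate",
    "scan_latent_variables",
    "vip_scores",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass
class NPLSModel:
    """Fitted tri-PLS1 model with everything needed to predict new cubes."""

    T: np.ndarray              # I x L scores
    WJ: np.ndarray             # J x L excitation weights (unit columns)
    WK: np.ndarray             # K x L emission weights (unit columns)
    P: np.ndarray              # (J*K) x L deflation loadings
    b: np.ndarray              # inner regression coefficients, length L
    x_means: np.ndarray        # J x K mode-1 centering state
    y_mean: float
    xvar_pct: np.ndarray       # cumulative % variation in X per LV
    yvar_pct: np.ndarray       # cumulative % variation in y per LV
    ex_values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    em_values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def L(self) -> int:
        return self.T.shape[1]

    @property
    def fitted(self) -> np.ndarray:
        """In-sample predicted response."""
        return self.y_mean + self.T @ self.b


@dataclass
class CVResult:
    s: int
    folds: np.ndarray
    y_pred_cv: np.ndarray
    rmsec: float
    rmsecv: float
    training_accuracy_pct: float
    validation_accuracy_pct: float


@dataclass
class VIPMap:
    """J x K grid of VIP values; squared VIPs average to 1 over variables."""

    scores: np.ndarray
    threshold: float = 0.8

    def important(self) -> np.ndarray:
        return self.scores > self.threshold


def encode_response(labels, positive: str) -> np.ndarray:
    """0/1 response column for a binary class vector (1 = ``positive``)."""
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise EEMError(f"expected exactly two classes, found {classes}")
    if positive not in classes:
        raise EEMError(f"positive class {positive!r} not among {classes}")
    y = np.array([1.0 if l == positive else 0.0 for l in labels])
    log.info("encode_response: %r -> 1, %r -> 0",
             positive, next(c for c in classes if c != positive))
    return y


def _center(cube_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = cube_data.mean(axis=0)
    return cube_data - means[None], means


def fit_npls(cube: EEMCube, y: np.ndarray, L: int) -> NPLSModel:
    """Fit a discriminant tri-PLS1 model with L latent variables.

    The cube is mode-1 mean-centered internally (idempotent if already
    centered) and the response is centered on its mean; predictions add
    the mean back.
    """
    y = np.asarray(y, dtype=float).ravel()
    I, J, K = cube.shape
    if y.size != I:
        raise EEMError("response length does not match sample count")
    if not 1 <= L <= I - 1:
        raise EEMError(f"L must satisfy 1 <= L <= I-1 = {I - 1}")
    if np.allclose(y, y[0]):
        raise EEMError("response has zero variance")

    Xc, means = _center(cube.data)
    Xu = Xc.reshape(I, J * K).copy()
    y_mean = float(y.mean())
    yc = y - y_mean

    ssx0 = float(np.sum(Xu * Xu))
    ssy0 = float(np.sum(yc * yc))
    T = np.empty((I, 0))
    WJ = np.empty((J, 0))
    WK = np.empty((K, 0))
    P = np.empty((J * K, 0))
    b = np.empty(0)
    xvar = []
    yvar = []
    r = yc.copy()
    for _ in range(L):
        Z = np.tensordot(r, Xu.reshape(I, J, K), axes=(0, 0))  # J x K
        U, _, Vt = np.linalg.svd(Z, full_matrices=False)
        wj, wk = U[:, 0], Vt[0]
        # deterministic sign: largest-|.| element of the composite positive
        if wj[np.argmax(np.abs(wj))] < 0:
            wj, wk = -wj, -wk
        w = np.outer(wj, wk).ravel()
        t = Xu @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            log.warning("fit_npls: degenerate LV (zero score variance); stopping early")
            break
        p = Xu.T @ t / tt
        Xu -= np.outer(t, p)  # projection deflation keeps scores orthogonal
        T = np.column_stack([T, t])
        WJ = np.column_stack([WJ, wj])
        WK = np.column_stack([WK, wk])
        P = np.column_stack([P, p])
        b, *_ = np.linalg.lstsq(T, yc, rcond=None)
        r = yc - T @ b
        xvar.append(100.0 * (1.0 - float(np.sum(Xu * Xu)) / ssx0))
        yvar.append(100.0 * (1.0 - float(np.sum(r * r)) / ssy0))

    return NPLSModel(
        T=T, WJ=WJ, WK=WK, P=P, b=b, x_means=means, y_mean=y_mean,
        xvar_pct=np.array(xvar), yvar_pct=np.array(yvar),
        ex_values=cube.ex.values.copy(), em_values=cube.em.values.copy(),
    )


def predict(
    model: NPLSModel, cube: EEMCube, threshold: float = DEFAULT_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Predict responses and classes for a cube on the training region.

    Applies the stored mode-1 centering, runs the stored weight/deflation
    sequence, and thresholds the predicted response (class 1 iff
    y_hat >= threshold; the boundary itself maps to class 1).
    """
    J, K = model.x_means.shape
    if cube.shape[1] != J or cube.shape[2] != K:
        raise EEMError("cube axes do not match the model's training region")
    if not (
        np.array_equal(cube.ex.values, model.ex_values)
        and np.array_equal(cube.em.values, model.em_values)
    ):
        raise EEMError("cube wavelength axes differ from the training axes")
    I = cube.n_samples
    Xu = (cube.data - model.x_means[None]).reshape(I, J * K).copy()
    Tn = np.empty((I, model.L))
    for f in range(model.L):
        w = np.outer(model.WJ[:, f], model.WK[:, f]).ravel()
        t = Xu @ w
        Tn[:, f] = t
        Xu -= np.outer(t, model.P[:, f])
    y_hat = model.y_mean + Tn @ model.b
    return y_hat, (y_hat >= threshold).astype(int)


def venetian_blinds_folds(I: int, s: int, offset: int = 0) -> np.ndarray:
    """Fold assignment fold(i) = (i + offset) mod s on the sample order."""
    if not 2 <= s <= I:
        raise EEMError(f"venetian blinds requires 2 <= s <= I, got s={s}, I={I}")
    return (np.arange(I) + offset) % s


def _accuracy_pct(y_true01: np.ndarray, y_hat: np.ndarray, threshold: float) -> float:
    pred = (y_hat >= threshold).astype(int)
    return 100.0 * float(np.mean(pred == y_true01))


def _cv_path(
    cube: EEMCube,
    y: np.ndarray,
    L_max: int,
    s: int,
    offset: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Fit the full model and all CV folds once, evaluating every L <= L_max.

    Because scores are orthogonal, the inner coefficients of the L-term
    model are the first L coefficients of the L_max-term model, so nested
    model predictions come for free from a single fit per fold.
    """
    y = np.asarray(y, dtype=float).ravel()
    I = cube.n_samples
    folds = venetian_blinds_folds(I, s, offset)
    full = fit_npls(cube, y, L_max)
    L_eff = full.L
    y01 = (y >= 0.5).astype(int)

    # per-L in-sample predictions from nested inner regressions
    fitted = full.y_mean + np.cumsum(full.T * full.b[None, :], axis=1)  # I x L
    y_pred_cv = np.full((I, L_eff), np.nan)
    for f in range(s):
        test = folds == f
        train = ~test
        if len(set(np.asarray(y01)[train].tolist())) < 2:
            log.warning("cross_validate: fold %d training set has a single class", f)
        sub = cube.subset(np.flatnonzero(train))
        m = fit_npls(sub, y[train], min(L_eff, int(train.sum()) - 1))
        # nested predictions for every L
        Xu = (cube.data[test] - m.x_means[None]).reshape(int(test.sum()), -1).copy()
        Tn = np.empty((int(test.sum()), m.L))
        for lv in range(m.L):
            w = np.outer(m.WJ[:, lv], m.WK[:, lv]).ravel()
            t = Xu @ w
            Tn[:, lv] = t
            Xu -= np.outer(t, m.P[:, lv])
        nested = m.y_mean + np.cumsum(Tn * m.b[None, :], axis=1)
        y_pred_cv[test, : m.L] = nested
        if m.L < L_eff:  # fold too small for all LVs: carry the last forward
            y_pred_cv[test, m.L :] = nested[:, [-1]]

    return {
        "model": full,
        "folds": folds,
        "fitted_per_L": fitted,
        "cv_per_L": y_pred_cv,
        "y": y,
        "y01": y01,
        "threshold": threshold,
    }


def cross_validate(
    cube: EEMCube,
    y: np.ndarray,
    L: int,
    s: int = 3,
    offset: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVResult:
    """Venetian-blinds cross-validation of an L-LV model.

    RMSEC is the root mean squared residual of the full-data fit; RMSECV
    pools the held-out predictions of all folds (each sample predicted
    exactly once).  Training folds are re-centered internally, so no
    information leaks from held-out samples.
    """
    path = _cv_path(cube, y, L, s, offset, threshold)
    L_eff = min(L, path["model"].L)  # rank-limited cubes stop early
    fitted = path["fitted_per_L"][:, L_eff - 1]
    y_cv = path["cv_per_L"][:, L_eff - 1]
    yv = path["y"]
    return CVResult(
        s=s,
        folds=path["folds"],
        y_pred_cv=y_cv,
        rmsec=float(np.sqrt(np.mean((yv - fitted) ** 2))),
        rmsecv=float(np.sqrt(np.mean((yv - y_cv) ** 2))),
        training_accuracy_pct=_accuracy_pct(path["y01"], fitted, threshold),
        validation_accuracy_pct=_accuracy_pct(path["y01"], y_cv, threshold),
    )


def scan_latent_variables(
    cube: EEMCube,
    y: np.ndarray,
    L_max: int = 20,
    s: int = 3,
    offsets: tuple[int, ...] = (0, 1, 2),
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-LV complexity scan, averaged over several venetian-blinds splits.

    Returns a table with one row per latent-variable count: cumulative
    % variation in X and y, training/validation accuracy, RMSEC and
    RMSECV, each as mean and SD over the requested fold offsets.
    """
    if L_max > cube.n_samples - 1:
        raise EEMError("L_max must be at most I - 1")
    per_offset = []
    for off in offsets:
        path = _cv_path(cube, y, L_max, s, off, threshold)
        m = path["model"]
        L_eff = m.L
        rows = []
        for L in range(1, L_eff + 1):
            fitted = path["fitted_per_L"][:, L - 1]
            y_cv = path["cv_per_L"][:, L - 1]
            yv = path["y"]
            rows.append(
                {
                    "L": L,
                    "xvar_pct": m.xvar_pct[L - 1],
                    "yvar_pct": m.yvar_pct[L - 1],
                    "training_accuracy_pct": _accuracy_pct(path["y01"], fitted, threshold),
                    "validation_accuracy_pct": _accuracy_pct(path["y01"], y_cv, threshold),
                    "rmsec": float(np.sqrt(np.mean((yv - fitted) ** 2))),
                    "rmsecv": float(np.sqrt(np.mean((yv - y_cv) ** 2))),
                }
            )
        per_offset.append(pd.DataFrame(rows).set_index("L"))
    stacked = pd.concat(per_offset, keys=range(len(offsets)))
    mean = stacked.groupby(level=1).mean()
    sd = stacked.groupby(level=1).std(ddof=1).fillna(0.0)
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
    out.index.name = "L"
    return out.reset_index()


def vip_scores(model: NPLSModel, y: np.ndarray) -> VIPMap:
    """Variable importance in projection over the excitation/emission grid.

    VIP(j,k) = sqrt( P * sum_f SSY_f * w_f(j,k)^2 / sum_f SSY_f ), where
    P = J*K, w_f is the unit-norm outer product of the LV's excitation and
    emission weights, and SSY_f is the response variance newly explained
    by LV f.  Squared VIPs average to exactly 1 over all variables; values
    below ~0.8 mark variables that contribute little to the discrimination.
    """
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    ssy0 = float(np.sum(yc * yc))
    cum = model.yvar_pct / 100.0 * ssy0
    ssy_f = np.diff(np.concatenate([[0.0], cum]))
    ssy_f = np.maximum(ssy_f, 0.0)
    total = float(ssy_f.sum())
    if total <= 0:
        raise EEMError("VIP undefined: model explains no response variance")
    J, K = model.WJ.shape[0], model.WK.shape[0]
    Pvars = J * K
    acc = np.zeros((J, K))
    for f in range(model.L):
        w = np.outer(model.WJ[:, f], model.WK[:, f])
        acc += ssy_f[f] * w**2
    vip = np.sqrt(Pvars * acc / total)
    return VIPMap(scores=vip)
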