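"""Fisher linear discriminant analysis on mode-1 scores.

The trilinear decompositions reduce each sample's EEM landscape to a short
score vector (relative fluorophore concentrations for PARAFAC, latent
variable scores for tri-PLS).  Two-class Fisher LDA finds the direction
maximizing between-class over within-class scatter in that score space and
classifies by the nearest class mean along it (equal priors).  Validated
performance uses the same venetian-blinds fold rule as the regression
module, holding out every sample exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from eemauth.eem_io import EEMError
from eemauth.npls import venetian_blinds_folds

__all__ = ["LDAResult", "fit_fisher_lda", "lda_cross_validate", "classification_report"]

log = logging.getLogger(__name__)


@dataclass
class LDAResult:
    direction: np.ndarray              # discriminant axis in score space
    coefficients_std: np.ndarray       # standardized scoring coefficients
    scores: np.ndarray                 # per-sample discriminant scores
    predictions: np.ndarray            # 0/1 predicted classes
    confusion: np.ndarray              # 2 x 2, rows = true class, cols = predicted
    accuracy_pct: float
    variable_correlations: np.ndarray  # Pearson r of each variable with the scores
    kind: str = "training"


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _fisher_direction(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Fisher axis and the decision midpoint of the projected class means."""
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for Xc, m in ((X0, m0), (X1, m1)):
        d = Xc - m
        Sw += d.T @ d
    D = X.shape[1]
    ridge = 1e-8 * np.trace(Sw) / D if np.trace(Sw) > 0 else 1e-8
    try:
        w = np.linalg.solve(Sw, m1 - m0)
    except np.linalg.LinAlgError:
        log.warning("fit_fisher_lda: singular within-class scatter; ridge-regularized")
        w = np.linalg.solve(Sw + ridge * np.eye(D), m1 - m0)
    if not np.all(np.isfinite(w)) or np.allclose(w, 0):
        w = np.linalg.solve(Sw + ridge * np.eye(D), m1 - m0)
    nw = np.linalg.norm(w)
    if nw > 0:
        w = w / nw
    midpoint = 0.5 * float(w @ (m0 + m1))
    # orient so class 1 projects above the midpoint
    if w @ m1 < w @ m0:
        w, midpoint = -w, -midpoint
    return w, midpoint


def fit_fisher_lda(scores: np.ndarray, labels: np.ndarray) -> LDAResult:
    """Fit two-class Fisher LDA and classify the training samples.

    ``labels`` is a 0/1 vector; classification is by nearest class mean
    along the discriminant direction (equal priors).  Standardized
    coefficients scale the direction by the pooled within-class standard
    deviation of each variable, making them comparable across variables.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise EEMError("scores must be I x D with one label per row")
    if set(y.tolist()) != {0, 1}:
        raise EEMError("labels must contain both classes 0 and 1")
    w, midpoint = _fisher_direction(X, y)
    proj = X @ w
    pred = (proj >= midpoint).astype(int)
    n0, n1 = (y == 0).sum(), (y == 1).sum()
    pooled_var = (
        ((X[y == 0] - X[y == 0].mean(0)) ** 2).sum(0)
        + ((X[y == 1] - X[y == 1].mean(0)) ** 2).sum(0)
    ) / max(n0 + n1 - 2, 1)
    coeff_std = w * np.sqrt(pooled_var)
    corr = np.empty(X.shape[1])
    for d in range(X.shape[1]):
        sd = X[:, d].std()
        corr[d] = (
            np.corrcoef(X[:, d], proj)[0, 1] if sd > 0 and proj.std() > 0 else 0.0
        )
    cm = _confusion(y, pred)
    return LDAResult(
        direction=w,
        coefficients_std=coeff_std,
        scores=proj,
        predictions=pred,
        confusion=cm,
        accuracy_pct=100.0 * float(np.mean(pred == y)),
        variable_correlations=corr,
        kind="training",
    )


def lda_cross_validate(
    scores: np.ndarray, labels: np.ndarray, s: int = 5, offset: int = 0
) -> LDAResult:
    """Venetian-blinds cross-validated Fisher LDA.

    Folds follow the sample order (fold = index mod s); each fold is
    predicted by a model refitted on the remaining samples, so with s = 5
    every model trains on 80% of the data.  Returns the pooled held-out
    classification.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    folds = venetian_blinds_folds(X.shape[0], s, offset)
    pred = np.empty_like(y)
    proj = np.empty(X.shape[0])
    for f in range(s):
        test = folds == f
        train = ~test
        if len(set(y[train].tolist())) < 2:
            raise EEMError(f"fold {f}: training set does not contain both classes")
        w, midpoint = _fisher_direction(X[train], y[train])
        p = X[test] @ w
        proj[test] = p
        pred[test] = (p >= midpoint).astype(int)
    cm = _confusion(y, pred)
    res = fit_fisher_lda(X, y)  # direction/coefficients from the full data
    return LDAResult(
        direction=res.direction,
        coefficients_std=res.coefficients_std,
        scores=proj,
        predictions=pred,
        confusion=cm,
        accuracy_pct=100.0 * float(np.mean(pred == y)),
        variable_correlations=res.variable_correlations,
        kind="cross-validation",
    )


def classification_report(result: LDAResult) -> dict:
    """JSON-ready report: confusion matrix, accuracy, coefficients, correlations."""
    cm = result.confusion
    acc = 100.0 * float(np.trace(cm)) / float(cm.sum()) if cm.sum() else float("nan")
    return {
        "kind": result.kind,
        "confusion": cm.tolist(),
        "accuracy_pct": result.accuracy_pct,
        "accuracy_from_confusion_pct": acc,
        "direction": result.direction.tolist(),
        "standardized_coefficients": result.coefficients_std.tolist(),
        "variable_correlations": result.variable_correlations.tolist(),
    }
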