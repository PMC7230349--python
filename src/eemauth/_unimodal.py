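"""Unimodal (single-peak) non-negative least-squares regression.

Used by constrained PARAFAC to force spectral loading columns to have
exactly one local maximum, which is what smooth excitation or emission
bands of a single fluorophore look like.  For a fixed peak position the
problem splits into an increasing isotonic fit on the left and a
decreasing one on the right; both are solved by pool-adjacent-violators
(PAVA), and the best peak is chosen by scanning all positions with
incrementally maintained prefix/suffix fits.  Non-negativity is exact:
clipping an isotonic solution at zero is the constrained optimum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unimodal_nonneg_regression"]


def _prefix_isotonic_sse(y: np.ndarray) -> np.ndarray:
    """SSE of the best increasing non-negative fit to y[:m+1], for every m.

    Maintains PAVA pools incrementally; O(n) amortized.  The SSE accounts
    for clipping pool means at zero (exact under the x >= 0 constraint).
    """
    n = y.size
    sse = np.empty(n)
    # pools: (sum, count, sumsq) with non-increasing means from the top
    sums: list[float] = []
    cnts: list[int] = []
    sqs: list[float] = []
    for m in range(n):
        s, c, q = float(y[m]), 1, float(y[m]) ** 2
        while sums and sums[-1] / cnts[-1] >= s / c:
            s += sums.pop()
            c += cnts.pop()
            q += sqs.pop()
        sums.append(s)
        cnts.append(c)
        sqs.append(q)
        total = 0.0
        for s_, c_, q_ in zip(sums, cnts, sqs):
            mean = max(s_ / c_, 0.0)  # non-negativity clip
            total += q_ - 2.0 * mean * s_ + c_ * mean * mean
        sse[m] = total
    return sse


def _isotonic_fit(y: np.ndarray) -> np.ndarray:
    """Increasing non-negative isotonic fit (plain PAVA, then clip at 0)."""
    sums = []
    cnts = []
    for v in y:
        s, c = float(v), 1
        while sums and sums[-1] / cnts[-1] >= s / c:
            s += sums.pop()
            c += cnts.pop()
        sums.append(s)
        cnts.append(c)
    out = np.empty(y.size)
    pos = 0
    for s, c in zip(sums, cnts):
        out[pos : pos + c] = max(s / c, 0.0)
        pos += c
    return out


def unimodal_nonneg_regression(y: np.ndarray) -> np.ndarray:
    """Best least-squares fit to y that is non-negative and unimodal.

    Unimodal means increasing up to some position m, decreasing after it
    (no constraint ties the two segments together at the split).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    if n == 1:
        return np.maximum(y, 0.0)
    # prefix_sse[m]: cost of increasing fit on y[0..m]
    prefix = _prefix_isotonic_sse(y)
    # suffix_sse[m]: cost of decreasing fit on y[m..]; decreasing fit of a
    # segment == increasing fit of its reverse
    suffix_rev = _prefix_isotonic_sse(y[::-1])
    suffix = suffix_rev[::-1]
    # split k: increasing on [0..k], decreasing on [k+1..]; k = n-1 means
    # fully increasing
    costs = np.empty(n)
    costs[: n - 1] = prefix[: n - 1] + suffix[1:]
    costs[n - 1] = prefix[n - 1]
    k = int(np.argmin(costs))
    left = _isotonic_fit(y[: k + 1])
    if k == n - 1:
        return left
    right = _isotonic_fit(y[k + 1 :][::-1])[::-1]
    return np.concatenate([left, right])
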