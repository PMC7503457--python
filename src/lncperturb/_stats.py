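"""Internal statistical helpers: Spearman correlation with a small-sample
exact p-value, and a vectorised row-wise Spearman for permutation replicates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

# below this sample size the t-approximation for the Spearman p-value is
# poor and full enumeration of rank permutations is cheap (9! = 362,880)
EXACT_SPEARMAN_N = 10


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Uses average ranks for ties. For n >= 10 the p-value comes from the
    t-distribution approximation; below that, from exact enumeration of all
    rank permutations of ``y``. Returns ``(nan, nan)`` when either vector is
    constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if n >= EXACT_SPEARMAN_N:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = _rank_corr(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = _rank_corr(rx, np.asarray(perm))
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return float(obs), count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of paired rows of two (m, k) matrices.

    Average ranks for ties; rows where either side is constant yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x and y must be matching (m, k) matrices")
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    out[denom == 0] = np.nan
    return out
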