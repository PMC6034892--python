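"""ROI-level statistics: attentional modulation index, paired t, Pearson r, FDR.

The attentional modulation index quantifies how much a region's response
increases when the ignored stimulus shares the attended feature:

    I_A = (A_Same - A_Different) / (A_Same + A_Different) * 100%

where A_Same and A_Different are mean block response amplitudes.  Group
inference uses classical paired/one-sample t tests and Pearson
correlations (two-tailed), with Benjamini–Hochberg FDR for families of
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "attention_index",
    "paired_t",
    "one_sample_t",
    "pearson_r",
    "fdr_bh",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic (t or r) with degrees of freedom and two-tailed p."""

    statistic: float
    df: int
    p: float
    kind: str = "t"

    def __iter__(self):
        return iter((self.statistic, self.df, self.p))


def attention_index(a_same: float, a_diff: float) -> float:
    """(a_same - a_diff) / (a_same + a_diff) * 100.

    Antisymmetric in its arguments; bounded in [-100, 100] when both
    amplitudes are nonnegative.  Raises if the denominator vanishes.
    """
    a_same = float(a_same)
    a_diff = float(a_diff)
    denom = a_same + a_diff
    if denom == 0.0:
        raise ZeroDivisionError("attention index undefined: a_same + a_diff == 0")
    return (a_same - a_diff) / denom * 100.0


def paired_t(x, y) -> StatResult:
    """Classical paired t test, df = n - 1, two-tailed p.

    Zero-variance differences are handled explicitly: all-zero
    differences give t = 0, p = 1; a constant nonzero difference gives
    an infinite t with p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return StatResult(0.0, df, 1.0)
        return StatResult(np.inf if mean > 0 else -np.inf, df, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(float(t), df, float(p))


def one_sample_t(x, popmean: float = 0.0) -> StatResult:
    """One-sample t against ``popmean`` (paired t of x against a constant)."""
    x = np.asarray(x, float)
    return paired_t(x, np.full_like(x, popmean))


def pearson_r(x, y) -> StatResult:
    """Pearson correlation with the t-transform p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("constant input: correlation undefined")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return StatResult(r, df, 0.0, kind="r")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(r, df, float(p), kind="r")


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
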