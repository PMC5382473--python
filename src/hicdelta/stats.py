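"""Shared statistical helpers: Wilcoxon signed-rank wrapper and BH adjustment.

The Wilcoxon convention used throughout: zero differences are dropped before
ranking; the exact null distribution is used for n < 25 when the absolute
differences are tie-free, otherwise the normal approximation with continuity
correction.  Groups with fewer than ``min_n`` usable pairs are reported as
untestable rather than given a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

EXACT_THRESHOLD = 25
MIN_TESTABLE = 3


@dataclass
class WilcoxonResult:
    n: int                  # usable (nonzero) differences
    statistic: float        # signed-rank statistic W (smaller-sum convention)
    p: float                # two-sided p; NaN when untestable
    median: float           # median of the usable differences
    testable: bool

    @property
    def direction(self) -> str:
        if not self.testable or self.median == 0:
            return "none"
        return "increase" if self.median > 0 else "decrease"


def signed_rank_test(diffs: np.ndarray) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against median zero."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    n = len(d)
    if n < MIN_TESTABLE:
        return WilcoxonResult(n=n, statistic=np.nan, p=np.nan, median=np.nan if n == 0 else float(np.median(d)), testable=False)
    has_ties = len(np.unique(np.abs(d))) < n
    if n < EXACT_THRESHOLD and not has_ties:
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = scipy.stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return WilcoxonResult(
        n=n,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        median=float(np.median(d)),
        testable=True,
    )


def paired_signed_rank(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on (x_i, y_i) pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return signed_rank_test(y - x)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
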