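"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the TAD oracle
enumerates every partition recursively; the Wilcoxon oracle enumerates every
sign assignment of the exact null distribution.
"""

import numpy as np

from hicdelta.tads import _scaled_density_table


def tad_brute_force_optimum(block, gamma, max_len=None):
    """Maximal sum(max(q, 0)) over all domain/background partitions.

    Uses the same per-interval quality values as the caller but explores the
    partition space exhaustively, summing left-to-right.
    """
    k = block.shape[0]
    if max_len is None:
        max_len = k
    s = _scaled_density_table(block, gamma, max_len)
    mu = np.nanmean(s, axis=0)
    q = s - mu[None, :]
    best = [0.0]

    def rec(pos, acc):
        if pos == k:
            if acc > best[0]:
                best[0] = acc
            return
        rec(pos + 1, acc)
        for length in range(1, min(max_len, k - pos) + 1):
            v = q[pos, length - 1]
            if np.isfinite(v) and v > 0:
                rec(pos + length, acc + v)

    rec(0, 0.0)
    return best[0]


_SIGN_MATRICES: dict[int, np.ndarray] = {}


def _sign_matrix(n: int) -> np.ndarray:
    if n not in _SIGN_MATRICES:
        codes = np.arange(2**n)[:, None]
        _SIGN_MATRICES[n] = ((codes >> np.arange(n)) & 1).astype(float)
    return _SIGN_MATRICES[n]


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided one-sample Wilcoxon p by full sign-flip enumeration.

    Assumes tie-free absolute differences (continuous data).  The statistic
    is |W+ - n(n+1)/4|, symmetric under the exchangeable-sign null.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.argsort(np.abs(d)))
    ranks = order + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    w_all = _sign_matrix(n) @ ranks
    return float(np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12))
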