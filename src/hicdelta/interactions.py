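"""Significant-interaction calling and feature/gene-set enrichment statistics.

The background model is a coverage x distance product: within each bin
distance stratum, a pair's expected count is proportional to the product of
its two bins' coverages, rescaled so that expected and observed counts sum to
the same total per stratum.  Significance is the upper-tail binomial
P(X >= obs | n = total cis count, p = expected / total), adjusted by
Benjamini-Hochberg.  Enrichment of feature sets at interaction ends is
measured against circular rotations of the feature labels within each
chromosome, which preserve the feature's own genomic clustering; the p-value
is a Wilcoxon signed-rank over per-chromosome observed-minus-expected pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import bins_of_positions, chrom_slices
from .matrix import ContactMatrix
from .stats import bh_adjust, signed_rank_test
from scipy.stats import binom

DEFAULT_N_RAND = 100


def call_significant_interactions(
    m: ContactMatrix,
    min_dist: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test all cis bin pairs at or beyond ``min_dist`` (bp; default 1 bin).

    Returns one row per tested pair with observed and expected counts, the
    binomial p-value, the BH q-value and a ``significant`` flag at the given
    FDR level.  Pairs involving a zero-coverage bin, or in a distance stratum
    with zero total counts, are excluded from testing.
    """
    if min_dist is None:
        min_dist = m.resolution
    if min_dist < m.resolution:
        raise ValueError("min_dist must be at least one bin")
    cov = m.coverage
    n_cis = m.cis_total()
    if n_cis <= 0:
        raise ValueError("matrix has zero cis counts")
    min_bins = min_dist // m.resolution

    rows_i, rows_j, rows_d, rows_obs, rows_w, rows_chrom = [], [], [], [], [], []
    for chrom, sl in m.chrom_slices().items():
        k = sl.stop - sl.start
        if k <= min_bins:
            continue
        iu = np.triu_indices(k, k=min_bins)
        gi = iu[0] + sl.start
        gj = iu[1] + sl.start
        keep = (cov[gi] > 0) & (cov[gj] > 0)
        gi, gj = gi[keep], gj[keep]
        rows_i.append(gi)
        rows_j.append(gj)
        rows_d.append(gj - gi)
        rows_obs.append(m.matrix[gi, gj])
        rows_w.append(cov[gi] * cov[gj])
        rows_chrom.append(np.full(len(gi), chrom, dtype=object))
    bi = np.concatenate(rows_i)
    bj = np.concatenate(rows_j)
    dist = np.concatenate(rows_d)
    obs = np.concatenate(rows_obs).astype(float)
    w = np.concatenate(rows_w).astype(float)
    chroms = np.concatenate(rows_chrom)

    expected = np.zeros_like(obs)
    for d in np.unique(dist):
        stratum = dist == d
        total = obs[stratum].sum()
        wsum = w[stratum].sum()
        if total > 0 and wsum > 0:
            expected[stratum] = total * w[stratum] / wsum
    keep = expected > 0
    bi, bj, dist, obs, expected, chroms = (
        bi[keep], bj[keep], dist[keep], obs[keep], expected[keep], chroms[keep],
    )
    p = binom.sf(obs - 1, int(round(n_cis)), expected / n_cis)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "bin_i": bi,
            "bin_j": bj,
            "distance_bp": dist * m.resolution,
            "observed": obs.astype(np.int64),
            "expected": expected,
            "p": p,
            "q": q,
            "significant": q < fdr,
        }
    )


@dataclass
class EnrichmentResult:
    observed: float
    expected: float
    log2_ratio: float
    p: float
    n_rand: int
    testable: bool
    per_chrom: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rotated_masks(
    mask: np.ndarray, slices: dict[str, slice], rng: np.random.Generator
) -> np.ndarray:
    out = mask.copy()
    for sl in slices.values():
        k = sl.stop - sl.start
        out[sl] = np.roll(mask[sl], int(rng.integers(k)))
    return out


def _count_hits_per_chrom(
    calls: pd.DataFrame,
    set_a: np.ndarray,
    set_b: np.ndarray,
    chrom_names: list[str],
    require_both_in_a: bool = False,
) -> np.ndarray:
    bi = calls["bin_i"].to_numpy()
    bj = calls["bin_j"].to_numpy()
    if require_both_in_a:
        hit = set_a[bi] & set_a[bj] & (bi != bj)
    else:
        hit = (set_a[bi] & set_b[bj]) | (set_b[bi] & set_a[bj])
    counts = np.zeros(len(chrom_names))
    chrom_idx = {c: i for i, c in enumerate(chrom_names)}
    for c, h in zip(calls["chrom"].to_numpy(), hit):
        counts[chrom_idx[c]] += bool(h)
    return counts


def feature_enrichment(
    calls: pd.DataFrame,
    bins: pd.DataFrame,
    set_a: np.ndarray,
    set_b: np.ndarray,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of calls joining a set-A bin to a set-B bin.

    ``set_a``/``set_b`` are boolean masks over the bin table.  Expected
    counts come from ``n_rand`` circular rotations of the set-B labels within
    each chromosome (set A stays fixed); the rotation preserves per-chromosome
    label counts exactly, so setB = all bins gives observed == expected and a
    log2 ratio of exactly zero.
    """
    if len(calls) == 0:
        raise ValueError("no interaction calls given")
    set_a = np.asarray(set_a, dtype=bool)
    set_b = np.asarray(set_b, dtype=bool)
    if not set_a.any() or not set_b.any():
        return EnrichmentResult(
            observed=np.nan, expected=np.nan, log2_ratio=np.nan, p=np.nan,
            n_rand=n_rand, testable=False,
        )
    slices = chrom_slices(bins)
    chrom_names = list(slices.keys())
    rng = np.random.default_rng(seed)
    obs_c = _count_hits_per_chrom(calls, set_a, set_b, chrom_names)
    exp_c = np.zeros(len(chrom_names))
    for _ in range(n_rand):
        rot = _rotated_masks(set_b, slices, rng)
        exp_c += _count_hits_per_chrom(calls, set_a, rot, chrom_names)
    exp_c /= n_rand
    return _summarize(obs_c, exp_c, chrom_names, n_rand)


def gene_set_clustering(
    calls: pd.DataFrame,
    bins: pd.DataFrame,
    gene_ids: list[str],
    expression: pd.DataFrame,
    resolution: int,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
) -> EnrichmentResult:
    """Clustering of a gene set: calls with both ends in set-TSS bins.

    The in-set bin mask (bins containing at least one of the set's TSSs) is
    rotated circularly per chromosome to form the expected count; self pairs
    (i == j) never count.  A set spanning fewer than two bins is untestable.
    """
    if len(calls) == 0:
        raise ValueError("no interaction calls given")
    mask = tss_bin_mask(gene_ids, expression, bins, resolution)
    if mask.sum() < 2:
        return EnrichmentResult(
            observed=np.nan, expected=np.nan, log2_ratio=np.nan, p=np.nan,
            n_rand=n_rand, testable=False,
        )
    slices = chrom_slices(bins)
    chrom_names = list(slices.keys())
    rng = np.random.default_rng(seed)
    obs_c = _count_hits_per_chrom(calls, mask, mask, chrom_names, require_both_in_a=True)
    exp_c = np.zeros(len(chrom_names))
    for _ in range(n_rand):
        rot = _rotated_masks(mask, slices, rng)
        exp_c += _count_hits_per_chrom(calls, rot, rot, chrom_names, require_both_in_a=True)
    exp_c /= n_rand
    return _summarize(obs_c, exp_c, chrom_names, n_rand)


def _summarize(
    obs_c: np.ndarray, exp_c: np.ndarray, chrom_names: list[str], n_rand: int
) -> EnrichmentResult:
    observed = float(obs_c.sum())
    expected = float(exp_c.sum())
    ratio = float(np.log2(observed / expected)) if expected > 0 and observed > 0 else (
        0.0 if observed == expected else np.nan
    )
    res = signed_rank_test(obs_c - exp_c)
    per_chrom = pd.DataFrame(
        {"chrom": chrom_names, "observed": obs_c, "expected": exp_c}
    )
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        log2_ratio=ratio,
        p=res.p,
        n_rand=n_rand,
        testable=res.testable,
        per_chrom=per_chrom,
    )


def interval_bin_mask(
    intervals: pd.DataFrame, bins: pd.DataFrame
) -> np.ndarray:
    """Boolean mask of bins overlapping any interval (chrom, start, end)."""
    mask = np.zeros(len(bins), dtype=bool)
    slices = chrom_slices(bins)
    bstart = bins["start"].to_numpy()
    bend = bins["end"].to_numpy()
    for _, iv in intervals.iterrows():
        sl = slices.get(iv["chrom"])
        if sl is None:
            continue
        over = (bstart[sl] < iv["end"]) & (bend[sl] > iv["start"])
        mask[sl] |= over
    return mask


def tss_bin_mask(
    gene_ids: list[str],
    expression: pd.DataFrame,
    bins: pd.DataFrame,
    resolution: int,
) -> np.ndarray:
    """Boolean mask of bins containing a TSS of any gene in the set."""
    sub = expression[expression["gene_id"].isin(set(gene_ids))]
    mask = np.zeros(len(bins), dtype=bool)
    if len(sub):
        ids = bins_of_positions(
            bins, resolution, sub["chrom"].to_numpy(), sub["tss"].to_numpy()
        )
        mask[ids[ids >= 0]] = True
    return mask
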