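"""Compartment switching, negatively correlated regions, and expression coupling.

Two condition comparisons are made at the bin level: (1) A/B label switches
for bins detectable in both conditions, with a per-class Wilcoxon test on
expression changes of resident genes; (2) per-bin correlation of contact
profiles between conditions, whose negative runs (r < 0) mark regions that
interact with different partners in the two states.  TSSs inside those
regions are split by the sign of the PC1 change and each gene group is given
a paired Wilcoxon test on raw FPKM values.

Zero-handling conventions: the switch-class test uses log2(FPKM+1) changes
and drops genes with zero change (the Wilcoxon zero convention); the paired
region test uses raw FPKM pairs, excludes genes at 0 in both conditions and
keeps genes at 0 in exactly one.  No multiple-testing correction is applied
across switch classes; raw p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import CompartmentTrack
from .genome import bins_of_positions, chrom_slices
from .stats import WilcoxonResult, paired_signed_rank, signed_rank_test

SWITCH_CLASSES = ["A->A", "A->B", "B->A", "B->B"]


def compartment_switches(
    t1: CompartmentTrack, t2: CompartmentTrack
) -> pd.DataFrame:
    """Per-bin switch classes for bins detectable in both conditions.

    Returns a DataFrame indexed by global bin id with columns
    ``label_1, label_2, switch_class``.
    """
    if not t1.bins[["chrom", "start", "end"]].equals(t2.bins[["chrom", "start", "end"]]):
        raise ValueError("bin tables differ between tracks")
    both = t1.detectable & t2.detectable & (t1.labels != "NA") & (t2.labels != "NA")
    idx = np.flatnonzero(both)
    l1 = t1.labels[idx]
    l2 = t2.labels[idx]
    return pd.DataFrame(
        {
            "label_1": l1,
            "label_2": l2,
            "switch_class": [f"{a}->{b}" for a, b in zip(l1, l2)],
        },
        index=pd.Index(idx, name="bin"),
    )


def switch_expression_test(
    switches: pd.DataFrame,
    expression: pd.DataFrame,
    cond_pair: tuple[str, str],
    bins: pd.DataFrame,
    resolution: int,
) -> pd.DataFrame:
    """Per switch class, Wilcoxon of log2(FPKM+1) changes of resident genes.

    Genes are assigned to bins by TSS; genes with exactly zero change are
    excluded; classes with fewer than three usable genes are untestable.
    """
    c1, c2 = cond_pair
    gene_bins = bins_of_positions(
        bins, resolution, expression["chrom"].to_numpy(), expression["tss"].to_numpy()
    )
    delta = np.log2(expression[f"fpkm_{c2}"].to_numpy(dtype=float) + 1.0) - np.log2(
        expression[f"fpkm_{c1}"].to_numpy(dtype=float) + 1.0
    )
    bin_class = dict(zip(switches.index.to_numpy(), switches["switch_class"]))
    rows = []
    for cls in SWITCH_CLASSES:
        member = np.array([bin_class.get(b) == cls for b in gene_bins])
        d = delta[member]
        res = signed_rank_test(d)
        rows.append(
            {
                "switch_class": cls,
                "n_genes": int(member.sum()),
                "n_tested": res.n,
                "statistic": res.statistic,
                "p": res.p,
                "median_delta": res.median,
                "direction": res.direction,
                "testable": res.testable,
            }
        )
    return pd.DataFrame(rows)


def correlation_diff(
    corr1: np.ndarray, corr2: np.ndarray, bins: pd.DataFrame
) -> np.ndarray:
    """Per-bin Pearson r of a bin's correlation profile between two conditions.

    Row i of condition 1 is correlated against row i of condition 2 over
    mutually defined columns, excluding column i itself; bins with fewer than
    three shared columns or zero variance get NaN.
    """
    n = len(bins)
    if corr1.shape != (n, n) or corr2.shape != (n, n):
        raise ValueError("correlation matrices do not match the bin table")
    out = np.full(n, np.nan)
    for sl in chrom_slices(bins).values():
        for i in range(sl.start, sl.stop):
            x = corr1[i, sl]
            y = corr2[i, sl]
            valid = ~np.isnan(x) & ~np.isnan(y)
            valid[i - sl.start] = False
            if valid.sum() < 3:
                continue
            xv = x[valid] - x[valid].mean()
            yv = y[valid] - y[valid].mean()
            denom = np.sqrt((xv**2).sum() * (yv**2).sum())
            if denom <= 1e-12:
                continue
            out[i] = float(xv @ yv / denom)
    return out


def find_negcorr_regions(
    r_per_bin: np.ndarray,
    bins: pd.DataFrame,
    delta_pc1: np.ndarray | None = None,
) -> pd.DataFrame:
    """Maximal runs of consecutive bins with r < 0 (single-bin runs allowed).

    Returns one row per region with global bin bounds, bp coordinates, the
    mean r over member bins and, when ``delta_pc1`` is given, its mean.
    """
    rows = []
    for chrom, sl in chrom_slices(bins).items():
        neg = np.zeros(sl.stop - sl.start, dtype=bool)
        seg = r_per_bin[sl]
        neg = np.where(np.isnan(seg), False, seg < 0)
        i = 0
        k = len(neg)
        while i < k:
            if not neg[i]:
                i += 1
                continue
            j = i
            while j + 1 < k and neg[j + 1]:
                j += 1
            lo, hi = sl.start + i, sl.start + j
            row = {
                "chrom": chrom,
                "bin_lo": lo,
                "bin_hi": hi,
                "start": int(bins["start"].iloc[lo]),
                "end": int(bins["end"].iloc[hi]),
                "n_bins": hi - lo + 1,
                "mean_r": float(np.nanmean(r_per_bin[lo:hi + 1])),
            }
            if delta_pc1 is not None:
                row["mean_delta_pc1"] = float(np.nanmean(delta_pc1[lo:hi + 1]))
            rows.append(row)
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "bin_lo", "bin_hi", "start", "end", "n_bins", "mean_r"]
        + (["mean_delta_pc1"] if delta_pc1 is not None else []),
    )


@dataclass
class TssGroup:
    direction: str          # 'decreased' or 'increased' PC1
    n_tss: int
    gene_ids: list[str]


def tss_pc1_partition(
    regions: pd.DataFrame,
    expression: pd.DataFrame,
    pc1_a: np.ndarray,
    pc1_b: np.ndarray,
    bins: pd.DataFrame,
    resolution: int,
) -> tuple[TssGroup, TssGroup]:
    """Split TSSs inside negatively correlated regions by the sign of delta PC1.

    A TSS is assigned by the PC1 change of its containing bin (condition b
    minus condition a); exact-zero changes are excluded.  Genes are
    deduplicated within each group (several TSS rows may share a gene id).
    """
    delta = np.asarray(pc1_b, dtype=float) - np.asarray(pc1_a, dtype=float)
    gene_bins = bins_of_positions(
        bins, resolution, expression["chrom"].to_numpy(), expression["tss"].to_numpy()
    )
    in_region = np.zeros(len(bins), dtype=bool)
    for _, reg in regions.iterrows():
        in_region[int(reg["bin_lo"]):int(reg["bin_hi"]) + 1] = True
    member = (gene_bins >= 0) & in_region[np.maximum(gene_bins, 0)]
    d = np.where(member, delta[np.maximum(gene_bins, 0)], np.nan)
    dec = member & (d < 0)
    inc = member & (d > 0)
    dec_ids = list(dict.fromkeys(expression.loc[dec, "gene_id"]))
    inc_ids = list(dict.fromkeys(expression.loc[inc, "gene_id"]))
    return (
        TssGroup(direction="decreased", n_tss=int(dec.sum()), gene_ids=dec_ids),
        TssGroup(direction="increased", n_tss=int(inc.sum()), gene_ids=inc_ids),
    )


def paired_expression_test(
    gene_ids: list[str],
    expression: pd.DataFrame,
    cond_pair: tuple[str, str],
) -> WilcoxonResult:
    """Paired Wilcoxon on raw FPKM pairs for a gene group.

    Genes with FPKM 0 in both conditions are excluded; genes at 0 in exactly
    one condition are kept.  Fewer than three usable pairs -> untestable.
    """
    c1, c2 = cond_pair
    sub = expression[expression["gene_id"].isin(set(gene_ids))]
    x = sub[f"fpkm_{c1}"].to_numpy(dtype=float)
    y = sub[f"fpkm_{c2}"].to_numpy(dtype=float)
    keep = ~((x == 0) & (y == 0))
    return paired_signed_rank(x[keep], y[keep])
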