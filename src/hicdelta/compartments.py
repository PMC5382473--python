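"""A/B compartment calling from the first principal component.

Per chromosome, PC1 is the leading eigenvector of the Pearson correlation
matrix of O/E contact profiles, restricted to detectable bins.  The raw
eigenvector sign is arbitrary; it is oriented so that PC1 correlates
positively with gene density (the A compartment is gene dense and
transcriptionally active), falling back to mean expression per bin when gene
density is flat.  After orientation, PC1 > 0 is called A, PC1 < 0 is B, and
masked bins (or an exact zero) are NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import chrom_slices

DEGENERATE_GAP = 1e-8


@dataclass
class CompartmentTrack:
    bins: pd.DataFrame
    condition: str
    resolution: int
    pc1: np.ndarray                 # oriented PC1, NaN for undetectable bins
    detectable: np.ndarray          # bool per bin
    labels: np.ndarray              # 'A' | 'B' | 'NA' per bin
    degenerate_chroms: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.copy()
        df["pc1"] = self.pc1
        df["detectable"] = self.detectable
        df["label"] = self.labels
        return df


def compute_pc1(
    corr: np.ndarray, bins: pd.DataFrame, mask: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Leading eigenvector (unit norm) of each chromosome's masked correlation matrix.

    Returns raw (unoriented) PC1 values, NaN at masked bins, and the list of
    chromosomes with a degenerate leading eigenpair (lambda1 - lambda2 below
    ``DEGENERATE_GAP``).  Sign is canonicalized to first-nonzero-positive so
    results are deterministic before orientation.
    """
    n = len(bins)
    pc1 = np.full(n, np.nan)
    degenerate: list[str] = []
    for chrom, sl in chrom_slices(bins).items():
        idx = np.flatnonzero(mask[sl]) + sl.start
        if len(idx) < 3:
            continue
        sub = corr[np.ix_(idx, idx)]
        sub = np.where(np.isnan(sub), 0.0, sub)
        sub = (sub + sub.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(sub)
        vec = eigvecs[:, -1]
        # A near-tied leading pair makes PC1 arbitrary; a (near-)constant
        # leading eigenvector carries no compartment contrast.  Flag both.
        if eigvals[-1] - eigvals[-2] < DEGENERATE_GAP or np.std(vec) < 1e-8:
            degenerate.append(chrom)
        nz = np.flatnonzero(np.abs(vec) > 1e-12)
        if len(nz) and vec[nz[0]] < 0:
            vec = -vec
        pc1[idx] = vec
    return pc1, degenerate


def orient_pc1(
    pc1: np.ndarray,
    bins: pd.DataFrame,
    gene_density: np.ndarray,
    mean_expression: np.ndarray | None = None,
) -> np.ndarray:
    """Flip PC1 per chromosome so it correlates non-negatively with gene density.

    Falls back to per-bin mean expression when gene density has zero variance
    over the chromosome's detectable bins; raises if both are degenerate.
    Orientation is idempotent.
    """
    out = pc1.copy()
    for chrom, sl in chrom_slices(bins).items():
        seg = out[sl]
        ok = ~np.isnan(seg)
        if ok.sum() < 3 or np.nanstd(seg[ok]) <= 1e-15:
            continue
        r = _safe_corr(seg[ok], np.asarray(gene_density, dtype=float)[sl][ok])
        if r is None:
            if mean_expression is None:
                raise ValueError(
                    f"gene density has zero variance on {chrom} and no expression fallback given"
                )
            r = _safe_corr(seg[ok], np.asarray(mean_expression, dtype=float)[sl][ok])
            if r is None:
                raise ValueError(f"cannot orient PC1 on {chrom}: both covariates degenerate")
        if r < 0:
            out[sl] = -seg
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(y) <= 1e-15 or np.std(x) <= 1e-15:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def call_compartments(
    pc1: np.ndarray,
    detectable: np.ndarray,
    bins: pd.DataFrame,
    condition: str,
    resolution: int,
    degenerate_chroms: list[str] | None = None,
) -> CompartmentTrack:
    """Label bins A (PC1 > 0), B (PC1 < 0) or NA (undetectable or PC1 == 0)."""
    labels = np.full(len(bins), "NA", dtype=object)
    usable = detectable & ~np.isnan(pc1)
    labels[usable & (pc1 > 0)] = "A"
    labels[usable & (pc1 < 0)] = "B"
    return CompartmentTrack(
        bins=bins,
        condition=condition,
        resolution=resolution,
        pc1=np.where(usable, pc1, np.nan),
        detectable=usable.astype(bool),
        labels=labels,
        degenerate_chroms=list(degenerate_chroms or []),
    )


def call_ab_compartments(
    corr: np.ndarray,
    bins: pd.DataFrame,
    mask: np.ndarray,
    gene_density: np.ndarray,
    condition: str,
    resolution: int,
    mean_expression: np.ndarray | None = None,
) -> CompartmentTrack:
    """Full chain: PC1 -> orientation -> A/B labels for one condition."""
    raw, degenerate = compute_pc1(corr, bins, mask)
    oriented = orient_pc1(raw, bins, gene_density, mean_expression)
    return call_compartments(
        oriented, mask & ~np.isnan(oriented), bins, condition, resolution, degenerate
    )


def ab_intervals(track: CompartmentTrack) -> pd.DataFrame:
    """Merge runs of identical A/B labels into BED-style intervals."""
    rows = []
    bins = track.bins
    labels = track.labels
    for chrom, sl in chrom_slices(bins).items():
        run_label = None
        run_start = None
        prev_end = None
        for i in range(sl.start, sl.stop):
            lab = labels[i]
            if lab == run_label and lab in ("A", "B"):
                prev_end = bins["end"].iloc[i]
                continue
            if run_label in ("A", "B"):
                rows.append((chrom, run_start, prev_end, run_label))
            run_label = lab
            run_start = bins["start"].iloc[i]
            prev_end = bins["end"].iloc[i]
        if run_label in ("A", "B"):
            rows.append((chrom, run_start, prev_end, run_label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def gene_density_per_bin(
    genes: pd.DataFrame, bins: pd.DataFrame, resolution: int
) -> np.ndarray:
    """Number of annotated TSSs per genome bin."""
    from .genome import bins_of_positions

    density = np.zeros(len(bins))
    if len(genes):
        ids = bins_of_positions(
            bins, resolution, genes["chrom"].to_numpy(), genes["tss"].to_numpy()
        )
        ids = ids[ids >= 0]
        np.add.at(density, ids, 1)
    return density


def mean_expression_per_bin(
    genes: pd.DataFrame, bins: pd.DataFrame, resolution: int, fpkm_column: str
) -> np.ndarray:
    """Mean log2(FPKM+1) of genes whose TSS falls in each bin (0 where empty)."""
    from .genome import bins_of_positions

    total = np.zeros(len(bins))
    count = np.zeros(len(bins))
    if len(genes):
        ids = bins_of_positions(
            bins, resolution, genes["chrom"].to_numpy(), genes["tss"].to_numpy()
        )
        keep = ids >= 0
        vals = np.log2(genes[fpkm_column].to_numpy(dtype=float) + 1.0)[keep]
        np.add.at(total, ids[keep], vals)
        np.add.at(count, ids[keep], 1)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), 0.0)
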