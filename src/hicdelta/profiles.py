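"""Expression-decile gene selections and strand-aware metagene PC1 profiles.

``select_deciles`` ranks significantly differentially expressed genes by
log2((FPKM2+1)/(FPKM1+1)) and takes the top/bottom fraction (default 10%).
``metagene_pc1`` averages the compartment PC1 signal in a +/-500 kb window
around each selected gene's TSS at 1 kb steps, reading the value of the
coarse bin containing each position (step-function interpolation) and
orienting the window by strand (negative offsets are upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import CompartmentTrack
from .genome import chrom_slices

DEFAULT_FRACTION = 0.10
DEFAULT_WINDOW = 500_000
DEFAULT_STEP = 1_000


@dataclass
class GeneSelection:
    comparison: str
    direction: str              # 'up' or 'down'
    fraction: float
    gene_ids: list[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_deciles(
    expression: pd.DataFrame,
    comparison: tuple[str, str],
    fraction: float = DEFAULT_FRACTION,
) -> tuple[GeneSelection, GeneSelection]:
    """Top and bottom fraction of significant genes by fold change.

    Only rows flagged significant for the comparison are ranked.  Ties are
    broken by a stable sort on (fold change, gene id); genes at FPKM 0 in
    both conditions have fold change exactly 0 and can never reach either
    extreme unless the significant set is tiny.
    """
    c1, c2 = comparison
    sig_col = f"sig_{c1}_vs_{c2}"
    if sig_col not in expression.columns:
        raise ValueError(f"no significance flags for comparison {c1} vs {c2}")
    sig = expression[expression[sig_col].astype(bool)].copy()
    if len(sig) == 0:
        raise ValueError("no significant genes for this comparison")
    fc = np.log2((sig[f"fpkm_{c2}"].to_numpy(dtype=float) + 1.0)
                 / (sig[f"fpkm_{c1}"].to_numpy(dtype=float) + 1.0))
    sig["_fc"] = fc
    ranked = sig.sort_values(["_fc", "gene_id"], kind="stable")
    n_sel = int(np.floor(fraction * len(ranked)))
    name = f"{c1}_vs_{c2}"
    down = GeneSelection(
        comparison=name, direction="down", fraction=fraction,
        gene_ids=list(ranked["gene_id"].iloc[:n_sel]),
    )
    up = GeneSelection(
        comparison=name, direction="up", fraction=fraction,
        gene_ids=list(ranked["gene_id"].iloc[len(ranked) - n_sel:]),
    )
    return up, down


def metagene_pc1(
    track: CompartmentTrack,
    gene_ids: list[str] | GeneSelection,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Mean PC1 per offset around the TSSs of a gene set.

    One TSS per gene (the first annotated row).  Offsets run from -window to
    +window in ``step`` increments; each genomic position takes the PC1 value
    of its containing resolution bin, positions off the chromosome ends or in
    undetectable bins are dropped from the mean.  Returns columns
    ``offset_bp, mean_pc1, n_genes``.
    """
    if isinstance(gene_ids, GeneSelection):
        gene_ids = gene_ids.gene_ids
    sub = annotation[annotation["gene_id"].isin(set(gene_ids))]
    sub = sub.drop_duplicates(subset="gene_id", keep="first")
    if len(sub) == 0:
        raise ValueError("empty gene list")
    offsets = np.arange(-window, window + step, step)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=np.int64)
    slices = chrom_slices(track.bins)
    res = track.resolution
    for _, gene in sub.iterrows():
        sl = slices.get(gene["chrom"])
        if sl is None:
            continue
        sign = 1 if gene["strand"] == "+" else -1
        pos = gene["tss"] + sign * offsets
        local = pos // res
        ok = (pos >= 0) & (sl.start + local < sl.stop)
        vals = np.full(len(offsets), np.nan)
        vals[ok] = track.pc1[sl.start + local[ok]]
        use = ~np.isnan(vals)
        total[use] += vals[use]
        count[use] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"offset_bp": offsets, "mean_pc1": mean, "n_genes": count})
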