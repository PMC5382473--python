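"""Di-tag artifact classification, deduplication and binning.

A di-tag is one mapped Hi-C read pair; each end carries (chrom, pos, strand)
with ``pos`` the 0-based 5' mapping coordinate, plus the restriction fragment
containing it.  The QC pipeline runs classify -> deduplicate -> bin, mirroring
the standard HiCUP-style artifact filters:

``same_dangling``      same fragment, inward strands, a 5' end within
                       ``DANGLING_WINDOW`` bp of a fragment boundary
``same_internal``      same fragment, inward strands, away from boundaries
                       (also same fragment with parallel strands)
``same_circularized``  same fragment, outward strands
``contiguous``         adjacent fragments, inward strands, 5'-5' span within
                       the size range: consistent with one un-digested molecule
``re_ligation``        adjacent fragments, inward strands otherwise
``wrong_size``         reconstructed Hi-C insert outside the size range
``valid``              everything else (cis or trans)

The reconstructed insert size sums, over the two ends, the distance from the
5' position to the restriction site the read points toward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import RestrictionMap, bins_of_positions
from .matrix import ContactMatrix

CATEGORIES = [
    "valid",
    "contiguous",
    "wrong_size",
    "re_ligation",
    "same_internal",
    "same_dangling",
    "same_circularized",
]

DITAG_COLUMNS = [
    "readname",
    "chrom1",
    "pos1",
    "strand1",
    "frag1",
    "chrom2",
    "pos2",
    "strand2",
    "frag2",
]

DEFAULT_SIZE_RANGE = (150, 800)
DANGLING_WINDOW = 10
DUP_KEY = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass
class FilterReport:
    counts: dict[str, int]
    n_duplicates: int
    n_cis_valid: int
    n_trans_valid: int
    distance_histogram: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_input(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(cat, self.counts.get(cat, 0)) for cat in CATEGORIES]
        rows.append(("duplicate", self.n_duplicates))
        rows.append(("cis_valid_unique", self.n_cis_valid))
        rows.append(("trans_valid_unique", self.n_trans_valid))
        return pd.DataFrame(rows, columns=["category", "count"])


def canonicalize(tags: pd.DataFrame) -> pd.DataFrame:
    """Order each di-tag's ends so the lower genomic coordinate comes first.

    The genome order is (chromosome name, position); strand and fragment
    columns travel with their end.
    """
    t = tags.copy()
    c1 = t["chrom1"].astype(str)
    c2 = t["chrom2"].astype(str)
    swap = (c1 > c2) | ((c1 == c2) & (t["pos1"] > t["pos2"]))
    for a, b in [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"), ("frag1", "frag2")]:
        if a in t.columns and b in t.columns:
            va, vb = t.loc[swap, a].copy(), t.loc[swap, b].copy()
            t.loc[swap, a] = vb
            t.loc[swap, b] = va
    return t


def _insert_size(
    rmap: RestrictionMap,
    chrom: np.ndarray,
    pos: np.ndarray,
    strand: np.ndarray,
    frag: np.ndarray,
) -> np.ndarray:
    """Distance from each 5' end to the restriction site its read points toward."""
    out = np.empty(len(pos), dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        starts = rmap.starts[c]
        length = rmap.chrom_lengths[c]
        f = frag[m]
        fs = starts[f]
        fe = np.where(f + 1 < len(starts), starts[np.minimum(f + 1, len(starts) - 1)], length)
        p = pos[m]
        plus = strand[m] == "+"
        out[m] = np.where(plus, fe - p, p - fs + 1)
    return out


def classify_ditags(
    tags: pd.DataFrame,
    rmap: RestrictionMap,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> pd.Series:
    """Assign each canonicalized di-tag to exactly one artifact category."""
    t = canonicalize(tags)
    n = len(t)
    chrom1 = t["chrom1"].to_numpy(dtype=object)
    chrom2 = t["chrom2"].to_numpy(dtype=object)
    pos1 = t["pos1"].to_numpy(dtype=np.int64)
    pos2 = t["pos2"].to_numpy(dtype=np.int64)
    strand1 = t["strand1"].to_numpy(dtype=object)
    strand2 = t["strand2"].to_numpy(dtype=object)

    frag1 = np.empty(n, dtype=np.int64)
    frag2 = np.empty(n, dtype=np.int64)
    for c in np.unique(np.r_[chrom1, chrom2]):
        m1 = chrom1 == c
        m2 = chrom2 == c
        if m1.any():
            frag1[m1] = rmap.fragments_of(c, pos1[m1])
        if m2.any():
            frag2[m2] = rmap.fragments_of(c, pos2[m2])

    insert = _insert_size(rmap, chrom1, pos1, strand1, frag1) + _insert_size(
        rmap, chrom2, pos2, strand2, frag2
    )

    cis = chrom1 == chrom2
    same_frag = cis & (frag1 == frag2)
    adjacent = cis & (np.abs(frag1 - frag2) == 1)
    inward = (strand1 == "+") & (strand2 == "-")
    outward = (strand1 == "-") & (strand2 == "+")
    span = pos2 - pos1

    near_boundary = np.zeros(n, dtype=bool)
    if same_frag.any():
        idx = np.flatnonzero(same_frag)
        for i in idx:
            fs, fe = rmap.fragment_bounds(chrom1[i], int(frag1[i]))
            near_boundary[i] = (pos1[i] - fs <= DANGLING_WINDOW) or (
                fe - 1 - pos2[i] <= DANGLING_WINDOW
            )

    size_min, size_max = size_range
    size_ok = (insert >= size_min) & (insert <= size_max)

    cat = np.full(n, "valid", dtype=object)
    cat[~size_ok] = "wrong_size"
    cat[adjacent & inward] = "re_ligation"
    cat[adjacent & inward & (span <= size_max)] = "contiguous"
    cat[same_frag] = "same_internal"
    cat[same_frag & inward & near_boundary] = "same_dangling"
    cat[same_frag & outward] = "same_circularized"
    return pd.Series(cat, index=tags.index, name="category")


def classify_ditag(
    tag: dict,
    rmap: RestrictionMap,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> str:
    """Classify a single di-tag (convenience scalar wrapper)."""
    df = pd.DataFrame([tag])
    return str(classify_ditags(df, rmap, size_range).iloc[0])


def deduplicate(tags: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep the first occurrence of each (chrom, pos, strand) coordinate pair.

    Tags must be canonicalized first so that swapped-end copies collapse.
    """
    unique = tags.drop_duplicates(subset=DUP_KEY, keep="first")
    return unique, len(tags) - len(unique)


def bin_ditags(
    tags: pd.DataFrame, bins: pd.DataFrame, resolution: int
) -> ContactMatrix:
    """Accumulate valid di-tags into a symmetric binned contact matrix."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = len(bins)
    mat = np.zeros((n, n), dtype=np.int64)
    if len(tags):
        b1 = bins_of_positions(bins, resolution, tags["chrom1"].to_numpy(), tags["pos1"].to_numpy())
        b2 = bins_of_positions(bins, resolution, tags["chrom2"].to_numpy(), tags["pos2"].to_numpy())
        if (b1 < 0).any() or (b2 < 0).any():
            raise ValueError("di-tag position beyond chromosome end")
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        np.add.at(mat, (lo, hi), 1)
        mat = mat + mat.T - np.diag(np.diagonal(mat))
    return ContactMatrix(bins=bins, matrix=mat, resolution=resolution)


def qc_pipeline(
    tags: pd.DataFrame,
    rmap: RestrictionMap,
    bins: pd.DataFrame,
    resolution: int,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> tuple[pd.DataFrame, ContactMatrix, FilterReport]:
    """classify -> deduplicate -> bin; returns unique valid tags, matrix, report."""
    t = canonicalize(tags)
    category = classify_ditags(t, rmap, size_range)
    counts = {cat: int((category == cat).sum()) for cat in CATEGORIES}
    valid = t[(category == "valid").to_numpy()]
    valid_unique, n_dup = deduplicate(valid)
    cis = valid_unique["chrom1"].to_numpy() == valid_unique["chrom2"].to_numpy()
    dist = np.abs(
        valid_unique["pos2"].to_numpy(dtype=np.int64)
        - valid_unique["pos1"].to_numpy(dtype=np.int64)
    )[cis]
    hist_edges = np.array([0, 1e4, 1e5, 1e6, 1e7, 1e8, np.inf])
    hist, _ = np.histogram(dist, bins=hist_edges)
    hist_df = pd.DataFrame(
        {"min_bp": hist_edges[:-1], "max_bp": hist_edges[1:], "n_pairs": hist}
    )
    report = FilterReport(
        counts=counts,
        n_duplicates=n_dup,
        n_cis_valid=int(cis.sum()),
        n_trans_valid=int(len(valid_unique) - cis.sum()),
        distance_histogram=hist_df,
    )
    matrix = bin_ditags(valid_unique, bins, resolution)
    return valid_unique, matrix, report
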