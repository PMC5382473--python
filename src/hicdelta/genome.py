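"""Genome bin tables and restriction-fragment maps.

Coordinates are 0-based half-open throughout (BED convention).  A genomic
position ``pos`` at bin resolution ``res`` lives in bin ``pos // res``; the
same floor rule assigns transcription start sites and di-tag ends to bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end"]


def make_bin_table(chrom_lengths: dict[str, int], resolution: int) -> pd.DataFrame:
    """Tile each chromosome into fixed-width bins.

    Returns a DataFrame with columns ``chrom, start, end`` sorted by
    (chromosome in the given order, start); the row index is the global bin id.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        n = -(-length // resolution)
        for k in range(n):
            rows.append((chrom, k * resolution, min((k + 1) * resolution, length)))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def chrom_slices(bins: pd.DataFrame) -> dict[str, slice]:
    """Map chromosome -> slice of global bin ids (bins are chromosome-contiguous)."""
    out: dict[str, slice] = {}
    chroms = bins["chrom"].to_numpy()
    starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
    bounds = np.r_[starts, len(chroms)]
    for i, s in enumerate(starts):
        out[chroms[s]] = slice(int(s), int(bounds[i + 1]))
    return out


def bin_of(bins: pd.DataFrame, resolution: int, chrom: str, pos: int) -> int:
    """Global bin id containing (chrom, pos); raises for positions off the end."""
    sl = chrom_slices(bins)[chrom]
    local = pos // resolution
    if pos < 0 or sl.start + local >= sl.stop:
        raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
    return sl.start + local


def bins_of_positions(
    bins: pd.DataFrame,
    resolution: int,
    chroms: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Vectorized bin assignment; returns -1 for positions off the chromosome."""
    slices = chrom_slices(bins)
    out = np.full(len(positions), -1, dtype=np.int64)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    for chrom, sl in slices.items():
        m = chroms == chrom
        if not m.any():
            continue
        local = positions[m] // resolution
        ok = (positions[m] >= 0) & (sl.start + local < sl.stop)
        ids = np.where(ok, sl.start + local, -1)
        out[m] = ids
    return out


@dataclass
class RestrictionMap:
    """Restriction fragments tiling each chromosome without gaps or overlaps.

    ``starts[chrom]`` holds fragment start positions (first element 0);
    fragment ``i`` spans ``[starts[i], starts[i+1])`` with the last fragment
    ending at the chromosome length.
    """

    starts: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], fragment_size: int) -> "RestrictionMap":
        if fragment_size <= 0:
            raise ValueError("fragment_size must be positive")
        starts = {
            chrom: np.arange(0, length, fragment_size, dtype=np.int64)
            for chrom, length in chrom_lengths.items()
        }
        return cls(starts=starts, chrom_lengths=dict(chrom_lengths))

    def n_fragments(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def fragment_of(self, chrom: str, pos: int) -> int:
        """Fragment index containing pos (0-based)."""
        s = self.starts[chrom]
        if pos < 0 or pos >= self.chrom_lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return int(np.searchsorted(s, pos, side="right") - 1)

    def fragments_of(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        s = self.starts[chrom]
        positions = np.asarray(positions)
        if (positions < 0).any() or (positions >= self.chrom_lengths[chrom]).any():
            raise ValueError(f"position outside chromosome {chrom}")
        return np.searchsorted(s, positions, side="right") - 1

    def fragment_bounds(self, chrom: str, index: int) -> tuple[int, int]:
        s = self.starts[chrom]
        if index < 0 or index >= len(s):
            raise KeyError(f"fragment {index} not in {chrom}")
        end = int(s[index + 1]) if index + 1 < len(s) else self.chrom_lengths[chrom]
        return int(s[index]), end

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom, s in self.starts.items():
            ends = np.r_[s[1:], self.chrom_lengths[chrom]]
            for i, (a, b) in enumerate(zip(s, ends)):
                rows.append((chrom, int(a), int(b), i))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])

    @classmethod
    def from_bed(cls, df: pd.DataFrame) -> "RestrictionMap":
        starts: dict[str, np.ndarray] = {}
        lengths: dict[str, int] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if s[0] != 0 or (s[1:] != e[:-1]).any():
                raise ValueError(f"fragments do not tile chromosome {chrom}")
            starts[chrom] = s
            lengths[chrom] = int(e[-1])
        return cls(starts=starts, chrom_lengths=lengths)
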