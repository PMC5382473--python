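"""Plain-text readers and writers for the pipeline's on-disk formats.

Formats are deliberately simple and diff-able: validPairs-like TSV for
di-tags, sparse-triplet TSV plus a bin-table BED for contact matrices,
bedGraph for PC1 tracks, BED for intervals, TSV (with ``#``-prefixed header
comments carrying parameters) for tables, and a flat ``key = value`` text
format for configuration.  Writers emit stable formatting so reruns under a
fixed seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .ditags import DITAG_COLUMNS
from .matrix import ContactMatrix

FLOAT_FORMAT = "%.6g"


def _write_with_comments(df: pd.DataFrame, path: Path, comments: dict[str, Any] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: Path, comments: dict[str, Any] | None = None) -> None:
    _write_with_comments(df, path, comments)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_validpairs(tags: pd.DataFrame, path: Path) -> None:
    """validPairs-like TSV: readname chr1 pos1 strand1 frag1 chr2 pos2 strand2 frag2."""
    _write_with_comments(tags[DITAG_COLUMNS], path, None)


def read_validpairs(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DITAG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"validPairs file missing columns: {missing}")
    return df


def write_bed(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FORMAT)


def read_bed(path: Path, names: list[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=names, comment="#")


def write_matrix(m: ContactMatrix, triplet_path: Path, bins_path: Path) -> None:
    """Sparse upper-triangle triplets (bin1 <= bin2) plus the bin table as BED."""
    iu = np.triu_indices(m.n_bins)
    counts = m.matrix[iu]
    nz = counts > 0
    df = pd.DataFrame(
        {"bin1": iu[0][nz], "bin2": iu[1][nz], "count": counts[nz].astype(np.int64)}
    )
    _write_with_comments(df, Path(triplet_path), {"resolution": m.resolution})
    bed = m.bins.copy()
    bed["index"] = np.arange(len(bed))
    write_bed(bed, bins_path)


def read_matrix(triplet_path: Path, bins_path: Path) -> ContactMatrix:
    bins = read_bed(bins_path, ["chrom", "start", "end", "index"])
    bins = bins.sort_values("index").reset_index(drop=True)[["chrom", "start", "end"]]
    resolution = None
    with open(triplet_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            if key.strip() == "resolution":
                resolution = int(value.strip())
    if resolution is None:
        raise ValueError(f"{triplet_path} lacks a '# resolution = N' header")
    trip = pd.read_csv(triplet_path, sep="\t", comment="#")
    n = len(bins)
    mat = np.zeros((n, n), dtype=np.int64)
    b1 = trip["bin1"].to_numpy()
    b2 = trip["bin2"].to_numpy()
    c = trip["count"].to_numpy()
    mat[b1, b2] = c
    mat[b2, b1] = c
    return ContactMatrix(bins=bins, matrix=mat, resolution=resolution)


def write_bedgraph(bins: pd.DataFrame, values: np.ndarray, path: Path) -> None:
    """bedGraph of a per-bin signal; NaN bins are skipped."""
    keep = ~np.isnan(values)
    df = bins.loc[keep, ["chrom", "start", "end"]].copy()
    df["value"] = values[keep]
    write_bed(df, path)


def write_config(params: dict[str, Any], path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key} = {params[key]}\n")


def read_config(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
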