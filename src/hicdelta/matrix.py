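"""Contact matrices: distance normalization, correlation matrices, replicate QC.

A :class:`ContactMatrix` stores a dense symmetric count matrix over a genome
bin table.  Off-diagonal entry (i, j) is the number of di-tags joining bins i
and j (stored symmetrically, counted once per unordered pair); the diagonal
holds within-bin pair counts.  ``total`` therefore sums the upper triangle
including the diagonal.

Normalization follows the standard compartment-analysis chain: per-chromosome
expected-by-distance, observed/expected ratios, and the Pearson correlation
matrix of O/E bin profiles whose leading eigenvector defines compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import chrom_slices

DEFAULT_DETECTABLE_FRACTION = 0.2


@dataclass
class ContactMatrix:
    bins: pd.DataFrame
    matrix: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")
        if (self.matrix < 0).any():
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def coverage(self) -> np.ndarray:
        """Per-bin coverage: row sums of the symmetric matrix."""
        return self.matrix.sum(axis=1)

    @property
    def total(self) -> float:
        """Total contact count (upper triangle including the diagonal)."""
        iu = np.triu_indices(self.n_bins)
        return float(self.matrix[iu].sum())

    def chrom_slices(self) -> dict[str, slice]:
        return chrom_slices(self.bins)

    def cis_total(self) -> float:
        tot = 0.0
        for sl in self.chrom_slices().values():
            block = self.matrix[sl, sl]
            iu = np.triu_indices(sl.stop - sl.start)
            tot += block[iu].sum()
        return float(tot)


@dataclass
class OEMatrix:
    """Observed/expected ratios; undefined entries (trans, zero expected) are NaN."""

    bins: pd.DataFrame
    values: np.ndarray
    resolution: int
    expected: dict[str, np.ndarray] = field(default_factory=dict)

    def chrom_slices(self) -> dict[str, slice]:
        return chrom_slices(self.bins)


def expected_by_distance(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Mean contact count per bin distance, per chromosome.

    ``expected[chrom][d]`` is the mean of counts over all cis bin pairs of
    that chromosome at bin distance d (d = 0 is the diagonal).  Chromosomes
    with a single bin get an empty profile.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, sl in m.chrom_slices().items():
        block = m.matrix[sl, sl]
        k = block.shape[0]
        if k < 2:
            out[chrom] = np.zeros(0)
            continue
        prof = np.empty(k)
        for d in range(k):
            prof[d] = np.diagonal(block, d).mean()
        out[chrom] = prof
    return out


def observed_over_expected(m: ContactMatrix) -> OEMatrix:
    """O/E ratio matrix; entries with zero expected and all trans entries are NaN."""
    n = m.n_bins
    values = np.full((n, n), np.nan)
    expected = expected_by_distance(m)
    for chrom, sl in m.chrom_slices().items():
        block = m.matrix[sl, sl].astype(float)
        k = block.shape[0]
        if k < 2:
            continue
        prof = expected[chrom]
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        exp = prof[d]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(exp > 0, block / exp, np.nan)
        values[sl, sl] = oe
    return OEMatrix(bins=m.bins, values=values, resolution=m.resolution, expected=expected)


def detectable_mask(
    m: ContactMatrix, fraction: float = DEFAULT_DETECTABLE_FRACTION
) -> np.ndarray:
    """Bins with coverage >= fraction * chromosome median coverage.

    This mask defines which bins carry a detectable compartment signal; it is
    applied before correlation/PCA.
    """
    cov = m.coverage
    mask = np.zeros(m.n_bins, dtype=bool)
    for sl in m.chrom_slices().values():
        med = np.median(cov[sl])
        mask[sl] = cov[sl] >= fraction * med
    return mask


def _pairwise_row_correlation(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of rows i, j over columns excluding i and j.

    ``rows`` is a k x k (sub)matrix with NaN marking undefined entries.  The
    column exclusion avoids self-inflation from the (i, j) entries themselves.
    """
    k = rows.shape[0]
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    if k < 3:
        return out
    if not np.isnan(rows).any():
        # Downdating: correlations over all columns minus the two excluded ones,
        # computed from full-row sums and the Gram matrix in O(k^2).
        S = rows.sum(axis=1)
        Q = rows @ rows.T
        diag = np.diagonal(rows)
        nn = k - 2
        # For pair (a, b): excluded column values are rows[a, a], rows[a, b]
        # (row a) and rows[b, a], rows[b, b] (row b).
        Ra_a = diag[:, None] * np.ones((1, k))      # rows[a, a]
        Ra_b = rows                                  # rows[a, b]
        Rb_a = rows.T                                # rows[b, a]
        Rb_b = np.ones((k, 1)) * diag[None, :]       # rows[b, b]
        sa = S[:, None] - Ra_a - Ra_b
        sb = S[None, :] - Rb_a - Rb_b
        qa = np.diagonal(Q)[:, None] - Ra_a**2 - Ra_b**2
        qb = np.diagonal(Q)[None, :] - Rb_a**2 - Rb_b**2
        qab = Q - Ra_a * Rb_a - Ra_b * Rb_b
        cov = qab - sa * sb / nn
        va = qa - sa**2 / nn
        vb = qb - sb**2 / nn
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(va * vb)
            r = np.where(denom > 1e-12, cov / denom, np.nan)
        np.fill_diagonal(r, 1.0)
        return r
    for a in range(k):
        for b in range(a + 1, k):
            valid = ~np.isnan(rows[a]) & ~np.isnan(rows[b])
            valid[a] = valid[b] = False
            if valid.sum() < 3:
                continue
            x = rows[a, valid]
            y = rows[b, valid]
            vx = x - x.mean()
            vy = y - y.mean()
            denom = np.sqrt((vx**2).sum() * (vy**2).sum())
            if denom <= 1e-12:
                continue
            out[a, b] = out[b, a] = float(vx @ vy / denom)
    return out


def correlation_matrix(oe: OEMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-chromosome Pearson correlation of bin O/E profiles.

    Returns a full genome-size square array; entries outside a chromosome
    block, or touching a masked bin, are NaN.  Zero-variance rows get NaN
    rows/columns; the diagonal is 1 where defined.
    """
    n = len(oe.bins)
    out = np.full((n, n), np.nan)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    for sl in oe.chrom_slices().values():
        sub_mask = mask[sl]
        idx = np.flatnonzero(sub_mask) + sl.start
        if len(idx) < 3:
            continue
        rows = oe.values[np.ix_(idx, idx)]
        corr = _pairwise_row_correlation(rows)
        out[np.ix_(idx, idx)] = corr
    return out


def matrix_correlation(a: ContactMatrix, b: ContactMatrix) -> float:
    """Pearson r between two matrices over cis upper-triangle entries.

    Only entries whose two bins have nonzero coverage in both matrices enter;
    used for replicate reproducibility reporting.
    """
    if not a.bins[["chrom", "start", "end"]].equals(b.bins[["chrom", "start", "end"]]):
        raise ValueError("bin tables differ between matrices")
    cov_ok = (a.coverage > 0) & (b.coverage > 0)
    xs, ys = [], []
    for sl in a.chrom_slices().values():
        k = sl.stop - sl.start
        iu = np.triu_indices(k, k=1)
        keep = cov_ok[sl][iu[0]] & cov_ok[sl][iu[1]]
        xs.append(a.matrix[sl, sl][iu][keep])
        ys.append(b.matrix[sl, sl][iu][keep])
    x = np.concatenate(xs).astype(float)
    y = np.concatenate(ys).astype(float)
    if len(x) < 2:
        raise ValueError("too few shared cis entries to correlate")
    return float(np.corrcoef(x, y)[0, 1])


def pool_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of replicate matrices sharing a bin table."""
    if not matrices:
        raise ValueError("no matrices to pool")
    first = matrices[0]
    pooled = first.matrix.astype(np.int64).copy()
    for m in matrices[1:]:
        if not m.bins[["chrom", "start", "end"]].equals(
            first.bins[["chrom", "start", "end"]]
        ):
            raise ValueError("bin tables differ between replicates")
        pooled += m.matrix.astype(np.int64)
    return ContactMatrix(bins=first.bins, matrix=pooled, resolution=first.resolution)
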