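"""Synthetic Hi-C + expression data with planted, recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: power-law distance decay, a plaid A/B compartment pattern with
condition-specific switches, TAD blocks enriched for internal contacts,
planted high-fold bin-pair interactions, and gene expression coupled to
compartment state.  Expected counts are built multiplicatively on a
distance-decay baseline and Poisson-sampled, so counts stay integer with
realistic variance.  All randomness flows from a single seed through
``numpy.random.SeedSequence``: identical seeds give byte-identical outputs.

Default parameter values are desk-scale study conditions chosen to mirror
mammalian Hi-C behaviour (decay exponent 1, ~5% trans mass, megabase-scale
compartment blocks at 400 kb resolution); none are fit to any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import RestrictionMap, chrom_slices, make_bin_table
from .matrix import ContactMatrix

CONDITION_NAMES = ["myoblast", "myotube", "myotube_arac"]

DITAG_INSERT_HALF = (75, 400)   # per-end distance to the pointed cut site


def condition_names(n: int) -> list[str]:
    if n <= len(CONDITION_NAMES):
        return CONDITION_NAMES[:n]
    return CONDITION_NAMES + [f"condition{i}" for i in range(4, n + 1)]


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length: int = 40_000_000
    resolution: int = 400_000
    n_conditions: int = 2
    decay_exponent: float = 1.0           # contact probability ~ distance^-alpha
    trans_mass: float = 0.05              # fraction of library in trans contacts
    compartment_block_len: int = 5        # bins per A/B block
    plaid_strength: float = 1.0           # same-compartment x(1+s), cross /(1+s)
    n_switched_bins: int = 10
    tad_lengths: tuple[int, ...] = (4, 6, 8)
    tad_enrichment: float = 2.0           # fold on intra-TAD pairs
    n_planted_pairs: int = 5
    planted_pair_fold: float = 10.0
    library_size: int = 1_000_000         # expected di-tag count per condition
    expression_effect: float = 2.0        # log2-FPKM shift for A-compartment genes
    expression_noise_sd: float = 0.5      # log2-FPKM, per condition
    genes_per_bin: float = 2.0            # mean TSS count per bin
    gene_density_ratio: float = 3.0       # A:B gene density
    baseline_log2_fpkm: float = 3.0
    gene_baseline_sd: float = 1.0         # gene-level baseline spread, shared
    zero_expression_fraction: float = 0.05
    background_de_fraction: float = 0.3   # non-switched genes flagged DE
    background_de_sd: float = 0.3
    duplicate_rate: float = 0.1
    artifact_rates: dict[str, float] = field(default_factory=dict)
    fragment_size: int = 4_000
    size_range: tuple[int, int] = (150, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.resolution <= 0 or self.chrom_length % self.resolution != 0:
            raise ValueError("resolution must divide chrom_length")
        if self.chrom_length // self.resolution < 1:
            raise ValueError("configuration yields zero bins")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")
        if self.n_switched_bins > self.total_bins:
            raise ValueError("more switched bins than bins")
        for name, rate in {"duplicate_rate": self.duplicate_rate,
                           "trans_mass": self.trans_mass,
                           "zero_expression_fraction": self.zero_expression_fraction,
                           "background_de_fraction": self.background_de_fraction,
                           **self.artifact_rates}.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name}={rate} outside [0, 1]")
        if sum(self.artifact_rates.values()) > 1.0:
            raise ValueError("artifact rates sum above 1")
        if self.plaid_strength < 0:
            raise ValueError("plaid_strength must be >= 0")
        if self.tad_enrichment < 1 or self.planted_pair_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.expression_noise_sd < 0:
            raise ValueError("expression noise sd must be non-negative")

    @property
    def bins_per_chrom(self) -> int:
        return self.chrom_length // self.resolution

    @property
    def total_bins(self) -> int:
        return self.n_chromosomes * self.bins_per_chrom

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}

    def bin_table(self) -> pd.DataFrame:
        return make_bin_table(self.chrom_lengths, self.resolution)

    def restriction_map(self) -> RestrictionMap:
        return RestrictionMap.uniform(self.chrom_lengths, self.fragment_size)


@dataclass
class PlantedTruth:
    bins: pd.DataFrame
    resolution: int
    conditions: list[str]
    labels: np.ndarray                     # (n_conditions, n_bins) of 'A'/'B'
    switched_bins: np.ndarray              # global bin ids
    tad_intervals: list[tuple[str, int, int]]   # chromosome-local, inclusive
    planted_pairs: list[tuple[int, int]]   # global bin pairs, i < j
    up_gene_ids: list[str] = field(default_factory=list)
    down_gene_ids: list[str] = field(default_factory=list)

    def labels_frame(self) -> pd.DataFrame:
        df = self.bins.copy()
        for c, name in enumerate(self.conditions):
            df[f"label_{name}"] = self.labels[c]
        df["switched"] = np.isin(np.arange(len(self.bins)), self.switched_bins)
        return df


def _seed_streams(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def plant_truth(config: SimulationConfig) -> PlantedTruth:
    """Lay out compartment labels, switches, TADs and planted pairs."""
    rng = _seed_streams(config, 1)[0]
    bins = config.bin_table()
    nb = config.bins_per_chrom
    base = np.empty(config.total_bins, dtype=object)
    for ci in range(config.n_chromosomes):
        local = (np.arange(nb) // config.compartment_block_len) % 2
        base[ci * nb:(ci + 1) * nb] = np.where(local == 0, "A", "B")
    switched = np.sort(rng.choice(config.total_bins, config.n_switched_bins, replace=False))
    labels = np.tile(base, (config.n_conditions, 1))
    for c in range(1, config.n_conditions):
        flip = labels[c, switched]
        labels[c, switched] = np.where(flip == "A", "B", "A")

    tads: list[tuple[str, int, int]] = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 0
        li = 0
        while config.tad_lengths and pos + config.tad_lengths[li % len(config.tad_lengths)] <= nb:
            length = config.tad_lengths[li % len(config.tad_lengths)]
            tads.append((chrom, pos, pos + length - 1))
            pos += length + 1
            li += 1

    pairs: set[tuple[int, int]] = set()
    if config.n_planted_pairs and nb >= 4:
        attempts = 0
        while len(pairs) < config.n_planted_pairs and attempts < 10000:
            attempts += 1
            ci = int(rng.integers(config.n_chromosomes))
            i = int(rng.integers(nb - 2))
            j = int(rng.integers(i + 2, nb))
            pairs.add((ci * nb + i, ci * nb + j))
    return PlantedTruth(
        bins=bins,
        resolution=config.resolution,
        conditions=condition_names(config.n_conditions),
        labels=labels,
        switched_bins=switched,
        tad_intervals=tads,
        planted_pairs=sorted(pairs),
    )


def expected_contact_matrix(
    config: SimulationConfig, truth: PlantedTruth, condition: int
) -> np.ndarray:
    """Expected (pre-Poisson) counts for one condition, library-scaled."""
    n = config.total_bins
    nb = config.bins_per_chrom
    E = np.zeros((n, n))
    labels = truth.labels[condition]
    slices = chrom_slices(truth.bins)
    for sl in slices.values():
        k = sl.stop - sl.start
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        base = np.maximum(d, 1).astype(float) ** (-config.decay_exponent)
        lab = labels[sl]
        same = lab[:, None] == lab[None, :]
        if config.plaid_strength > 0:
            f = np.where(same, 1.0 + config.plaid_strength, 1.0 / (1.0 + config.plaid_strength))
            base = base * f
        E[sl, sl] = base
    for chrom, s, e in truth.tad_intervals:
        sl = slices[chrom]
        E[sl.start + s:sl.start + e + 1, sl.start + s:sl.start + e + 1] *= config.tad_enrichment
    for i, j in truth.planted_pairs:
        E[i, j] *= config.planted_pair_fold
        E[j, i] *= config.planted_pair_fold

    cis_mask = np.zeros((n, n), dtype=bool)
    for sl in slices.values():
        cis_mask[sl, sl] = True
    has_trans = config.n_chromosomes > 1 and config.trans_mass > 0
    cis_target = config.library_size * (1.0 - (config.trans_mass if has_trans else 0.0))
    iu = np.triu_indices(n)
    upper_cis = cis_mask[iu]
    cis_sum = E[iu][upper_cis].sum()
    E[cis_mask] *= cis_target / cis_sum
    if has_trans:
        n_trans_pairs = int((~upper_cis).sum())
        E[~cis_mask] = config.library_size * config.trans_mass / n_trans_pairs
    return E


def simulate_contact_maps(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> tuple[dict[str, ContactMatrix], PlantedTruth]:
    """Poisson-sample one contact matrix per condition around the expected model."""
    if truth is None:
        truth = plant_truth(config)
    rngs = _seed_streams(config, 1 + config.n_conditions)[1:]
    n = config.total_bins
    iu = np.triu_indices(n)
    out: dict[str, ContactMatrix] = {}
    for c, name in enumerate(truth.conditions):
        E = expected_contact_matrix(config, truth, c)
        counts = np.zeros((n, n), dtype=np.int64)
        counts[iu] = rngs[c].poisson(E[iu])
        counts = counts + counts.T - np.diag(np.diagonal(counts))
        out[name] = ContactMatrix(bins=truth.bins, matrix=counts, resolution=config.resolution)
    return out, truth


# --- di-tag stream ---------------------------------------------------------

def _sample_valid_ends(
    rng: np.random.Generator,
    rmap: RestrictionMap,
    chrom: str,
    bin_start: int,
    bin_end: int,
    forbidden_frag: int | None = None,
) -> tuple[int, str, int]:
    """One read end inside [bin_start, bin_end) positioned to pass QC."""
    starts = rmap.starts[chrom]
    f_lo = int(np.searchsorted(starts, bin_start, side="right") - 1)
    if starts[f_lo] < bin_start:
        f_lo += 1
    f_hi = int(np.searchsorted(starts, bin_end - 1, side="right") - 1)
    choices = [f for f in range(f_lo, f_hi + 1)
               if forbidden_frag is None or abs(f - forbidden_frag) >= 2]
    f = int(choices[rng.integers(len(choices))])
    fs, fe = rmap.fragment_bounds(chrom, f)
    u = int(rng.integers(DITAG_INSERT_HALF[0], DITAG_INSERT_HALF[1] + 1))
    if rng.integers(2):
        return fe - u, "+", f
    return fs + u - 1, "-", f


def simulate_ditags(
    config: SimulationConfig,
    truth: PlantedTruth,
    matrix: ContactMatrix,
) -> pd.DataFrame:
    """Emit a di-tag stream whose valid unique tags bin back to ``matrix``.

    Artifact tags are added at the configured per-category rates and exact
    duplicates of valid tags at ``duplicate_rate``; every row carries its true
    category in the ``truth_category`` column (the hidden truth channel, not
    written to validPairs output).
    """
    rng = _seed_streams(config, 8)[7]
    rmap = config.restriction_map()
    bins = truth.bins
    n = len(bins)
    iu = np.triu_indices(n)
    counts = matrix.matrix[iu]
    nonzero = counts > 0
    pair_i = iu[0][nonzero]
    pair_j = iu[1][nonzero]
    pair_c = counts[nonzero].astype(int)

    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()

    rows: list[tuple] = []
    seen: set[tuple] = set()
    for bi, bj, c in zip(pair_i, pair_j, pair_c):
        for _ in range(int(c)):
            for _attempt in range(100):
                p1, s1, f1 = _sample_valid_ends(rng, rmap, chroms[bi], starts[bi], ends[bi])
                forbidden = f1 if chroms[bi] == chroms[bj] else None
                p2, s2, f2 = _sample_valid_ends(rng, rmap, chroms[bj], starts[bj], ends[bj], forbidden)
                if chroms[bi] == chroms[bj] and p1 > p2:
                    p1, s1, f1, p2, s2, f2 = p2, s2, f2, p1, s1, f1
                key = (chroms[bi], p1, s1, chroms[bj], p2, s2)
                if key not in seen:
                    seen.add(key)
                    break
            else:  # pragma: no cover - effectively impossible at desk scale
                raise RuntimeError("could not find a unique di-tag coordinate")
            rows.append((chroms[bi], p1, s1, f1, chroms[bj], p2, s2, f2, "valid"))

    n_valid = len(rows)
    art_total_rate = sum(config.artifact_rates.values())
    stream_total = int(round(n_valid / (1.0 - art_total_rate))) if art_total_rate else n_valid
    for cat, rate in sorted(config.artifact_rates.items()):
        for _ in range(int(round(rate * stream_total))):
            rows.append(_artifact_tag(rng, rmap, config, cat))

    df = pd.DataFrame(
        rows,
        columns=["chrom1", "pos1", "strand1", "frag1",
                 "chrom2", "pos2", "strand2", "frag2", "truth_category"],
    )
    if config.duplicate_rate > 0 and n_valid > 0:
        r = config.duplicate_rate
        n_dup = int(rng.binomial(len(df), r / (1.0 - r)))
        picks = rng.integers(0, n_valid, size=n_dup)   # duplicate valid molecules
        dups = df.iloc[picks].copy()
        dups["truth_category"] = "duplicate"
        df = pd.concat([df, dups], ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "readname", [f"tag_{i:07d}" for i in range(len(df))])
    return df


def _artifact_tag(
    rng: np.random.Generator,
    rmap: RestrictionMap,
    config: SimulationConfig,
    category: str,
) -> tuple:
    chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
    nf = rmap.n_fragments(chrom)
    fsize = config.fragment_size
    size_max = config.size_range[1]
    if category in ("same_dangling", "same_internal", "same_circularized"):
        f = int(rng.integers(1, nf - 1))
        fs, fe = rmap.fragment_bounds(chrom, f)
        if category == "same_dangling":
            p1 = fs + int(rng.integers(0, 11))
            p2 = min(fe - 1, p1 + int(rng.integers(100, 400)))
            s1, s2 = "+", "-"
        elif category == "same_internal":
            p1 = fs + 12 + int(rng.integers(0, max(1, fsize // 4)))
            p2 = min(fe - 12, p1 + int(rng.integers(50, fsize // 2)))
            if p2 <= p1:
                p2 = p1 + 1
            s1, s2 = "+", "-"
        else:
            p1 = fs + int(rng.integers(0, fsize // 4))
            p2 = min(fe - 1, p1 + int(rng.integers(100, fsize // 2)))
            s1, s2 = "-", "+"
        return (chrom, p1, s1, f, chrom, p2, s2, f, category)
    if category in ("re_ligation", "contiguous"):
        f = int(rng.integers(0, nf - 1))
        boundary = int(rmap.starts[chrom][f + 1])
        if category == "contiguous":
            p1 = boundary - int(rng.integers(50, min(350, size_max // 2)))
            p2 = boundary + int(rng.integers(50, min(350, size_max // 2)))
        else:
            p1 = boundary - fsize + int(rng.integers(0, fsize // 2))
            p2 = boundary + size_max + 1 + int(rng.integers(0, fsize // 2))
            p2 = min(p2, boundary + fsize - 1)
        return (chrom, p1, "+", f, chrom, p2, "-", f + 1, category)
    if category == "wrong_size":
        f1 = int(rng.integers(0, nf - 4))
        f2 = f1 + 2 + int(rng.integers(0, 2))
        p1 = int(rmap.starts[chrom][f1]) + fsize // 2
        p2 = int(rmap.starts[chrom][f2]) + fsize // 2
        return (chrom, p1, "+", f1, chrom, p2, "-", f2, category)
    raise ValueError(f"unknown artifact category: {category}")


# --- expression ------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, truth: PlantedTruth
) -> pd.DataFrame:
    """Per-gene FPKM table coupled to compartment state, with planted DE truth.

    log2 FPKM = gene baseline + effect * 1[bin is A in that condition] + noise.
    Gene density is higher in A bins (``gene_density_ratio``), mirroring the
    gene-dense euchromatic compartment.  A configurable fraction of genes is
    zeroed in a random nonempty subset of conditions.  Genes in switched bins
    become the planted up-/down-regulated sets; a background fraction of other
    genes gets small shifts and a significance flag so ranked selections have
    a realistic pool.
    """
    rng = _seed_streams(config, 8)[6]
    bins = truth.bins
    base_labels = truth.labels[0]
    lam_b = 2.0 * config.genes_per_bin / (1.0 + config.gene_density_ratio)
    lam_a = config.gene_density_ratio * lam_b

    rows = []
    for b in range(len(bins)):
        lam = lam_a if base_labels[b] == "A" else lam_b
        k = int(rng.poisson(lam))
        for _ in range(k):
            tss = int(rng.integers(bins["start"].iloc[b], bins["end"].iloc[b]))
            strand = "+" if rng.integers(2) else "-"
            rows.append((bins["chrom"].iloc[b], tss, strand, b))
    genes = pd.DataFrame(rows, columns=["chrom", "tss", "strand", "bin"])
    genes = genes.sort_values(["bin", "tss"], kind="stable").reset_index(drop=True)
    genes.insert(0, "gene_id", [f"gene_{i:05d}" for i in range(len(genes))])

    ng = len(genes)
    n_cond = config.n_conditions
    baseline = config.baseline_log2_fpkm + rng.normal(0.0, config.gene_baseline_sd, ng)
    bin_ids = genes["bin"].to_numpy()
    in_switched = np.isin(bin_ids, truth.switched_bins)
    background = (~in_switched) & (rng.random(ng) < config.background_de_fraction)

    log2fpkm = np.empty((n_cond, ng))
    for c in range(n_cond):
        is_a = truth.labels[c][bin_ids] == "A"
        x = baseline + config.expression_effect * is_a
        if config.expression_noise_sd > 0:
            x = x + rng.normal(0.0, config.expression_noise_sd, ng)
        if c > 0:
            x = x + np.where(background, rng.normal(0.0, config.background_de_sd, ng), 0.0)
        log2fpkm[c] = x
    fpkm = 2.0 ** log2fpkm

    if config.zero_expression_fraction > 0 and ng:
        zero_genes = np.flatnonzero(rng.random(ng) < config.zero_expression_fraction)
        for g in zero_genes:
            which = rng.random(n_cond) < 0.6
            if not which.any():
                which[int(rng.integers(n_cond))] = True
            fpkm[which, g] = 0.0

    out = genes.drop(columns=["bin"]).copy()
    for c, name in enumerate(truth.conditions):
        out[f"fpkm_{name}"] = fpkm[c]
    significant = in_switched | background
    for c1 in range(n_cond):
        for c2 in range(c1 + 1, n_cond):
            out[f"sig_{truth.conditions[c1]}_vs_{truth.conditions[c2]}"] = significant

    if n_cond >= 2:
        went_up = (truth.labels[0][bin_ids] == "B") & (truth.labels[1][bin_ids] == "A")
        went_down = (truth.labels[0][bin_ids] == "A") & (truth.labels[1][bin_ids] == "B")
        truth.up_gene_ids = list(out.loc[went_up, "gene_id"])
        truth.down_gene_ids = list(out.loc[went_down, "gene_id"])
    return out
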