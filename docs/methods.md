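# Methods

`hicdelta` implements a condition-comparison analysis of 3D genome
organization and transcription: it takes binned Hi-C contact evidence and
per-gene expression for two or more cellular states (the canonical use case
is muscle differentiation: proliferating myoblasts versus differentiated
myotubes, with an optional AraC-purified myotube state) and asks where the
genome's compartment structure, domain structure and point interactions
change, and whether those changes track expression. This note records the
models, parameter choices and numerical conventions, and what the synthetic
validation does and does not establish.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention). A position `pos` at
resolution `res` belongs to bin `pos // res`; the same floor rule assigns
TSSs and di-tag ends. Contact matrices are symmetric; entry (i, j) counts
unordered di-tag pairs joining bins i and j, the diagonal counts within-bin
pairs once, and the matrix "total" is the upper triangle including the
diagonal — so the total equals the number of valid di-tags binned, which is
the conservation contract the QC stage is tested against.

## Di-tag QC

Di-tags are classified into HiCUP-style artifact categories with an explicit
rule table (the reference pipelines name the categories but not machine-
checkable rules, so the rules here are stated choices):

- same fragment + inward strands: `same_dangling` if either 5' end is within
  10 bp of a fragment boundary, else `same_internal`; same fragment +
  parallel strands is also `same_internal` (not covered by the usual
  taxonomy; folded in to keep classification exhaustive).
- same fragment + outward strands: `same_circularized`.
- adjacent fragments + inward strands: `contiguous` when the 5'-to-5'
  genomic span fits the sonication size range (consistent with one
  un-digested molecule spanning the cut site), else `re_ligation`.
  Distinguishing re-ligation from contiguity rigorously requires read
  sequence across the junction, which this pipeline does not model; the
  span rule is the best mapping-coordinate proxy and is deterministic.
- reconstructed insert outside the size range (default 150–800 bp):
  `wrong_size`. The insert sums, per end, the distance from the 5' position
  to the restriction site the read points toward.
- everything else is `valid` (cis or trans).

Deduplication keys on (chrom, pos, strand) of both canonicalized ends —
coordinates and strands define a molecule; read names and fragment ids do
not. The pipeline order is fixed: classify, deduplicate, bin.

## Normalization and compartments

Expected counts are the per-chromosome mean at each bin distance; O/E is
observed over that mean, so the distance-stratified mean of defined O/E
entries is 1 by construction (an identity the tests assert exactly). The
compartment signal is the leading eigenvector (PC1) of the per-chromosome
Pearson correlation matrix of O/E bin profiles; when correlating bins i and
j, columns i and j are excluded to avoid self-inflation. Bins with coverage
below 20% of the chromosome median are masked first, and this mask defines
"detectable" bins throughout — a stated, testable stand-in for the informal
notion of bins with a callable PC1.

Eigenvectors come from a deterministic dense symmetric solver; a chromosome
is flagged degenerate when the two leading eigenvalues are within 1e-8 *or*
the leading eigenvector is (near-)constant — a constant PC1 carries no
compartment contrast even when its eigenvalue is unique. The raw sign is
arbitrary, so PC1 is flipped per chromosome to correlate non-negatively with
gene density (the A compartment is gene dense); if gene density is flat the
orientation falls back to mean expression per bin, and if both are
degenerate it is an error rather than a silent guess. After orientation,
PC1 > 0 is A, PC1 < 0 is B, and exactly 0 is NA so the A/B definitions are
exclusive.

## Differential structure

Switches are classified per bin (A→A, A→B, B→A, B→B) over bins detectable
in both conditions. The per-class expression test is a two-sided one-sample
Wilcoxon signed-rank on log2(FPKM+1) changes of resident genes (TSS
assignment); zero changes are dropped (the Wilcoxon zero convention, which
also matches the analysis convention of excluding unchanged genes), and
classes with fewer than three usable genes are reported untestable. No
multiple-testing correction is applied across the four classes; the output
says so in its header.

Regions that rewire their contacts are found by correlating each bin's
correlation-matrix row between conditions (mutually defined columns,
excluding the bin's own column); maximal runs of r < 0 — single bins count —
are the negatively correlated regions. TSSs inside them are split by the
sign of the bin-level PC1 change (exact zeros excluded), genes deduplicated
per group, and each group is tested with a paired Wilcoxon on raw FPKM
pairs, excluding genes at 0 in both conditions but keeping genes at 0 in
exactly one. Whether the row correlation should be computed on correlation
matrices or O/E rows is genuinely open; correlation-matrix rows are used
here because the compartment analysis is already defined on them.

Wilcoxon implementation: exact null distribution for n < 25 without ties in
|differences|, normal approximation with continuity correction otherwise
(scipy backend). The test suite checks the exact branch against a full
sign-flip enumeration oracle on 1000 tie-free fixtures.

## TAD calling

A domain [k, l] scores s = (sum of strictly-upper-triangle counts inside) /
(l−k+1)^gamma; its quality q subtracts the mean s of all same-length
intervals on the chromosome, so only intervals denser than typical for
their size are rewarded. A dynamic program maximizes the sum of max(q, 0)
over partitions into domains and background bins; domains with q ≤ 0 are
never emitted (a zero matrix yields no domains). Ties are resolved
deterministically by the left-to-right scan preferring background, then
shorter domains. Gamma defaults to 0.5 with a single-gamma caller —
multi-gamma consensus is out of scope — and domain length is capped at 100
bins for O(n·L) runtime. Optimality is verified against exhaustive
partition enumeration on matrices up to 12 bins (exact float equality: both
routes sum the identical q values left to right) and against randomized
search on larger ones. Boundary conservation between conditions counts
domains with exactly identical bin bounds, reported in both directions;
conservation fractions are parameter-dependent (notably on gamma) and are
not comparable across gamma choices.

## Significant interactions and enrichment

The background for a cis pair at bin distance d is proportional to the
product of its bins' coverages, rescaled within each distance stratum so
expected and observed sums match exactly (also asserted in tests). The
p-value is the upper binomial tail P(X ≥ obs) with n the total cis count,
chosen over Poisson for boundedness; q-values are Benjamini–Hochberg.
Pairs involving zero-coverage bins, or in strata with zero total counts,
are not tested. Only cis pairs at ≥ 1 bin separation are tested; trans
calling is off.

Known limitation: when distance decay is steep, per-bin coverage varies
geometrically (chromosome-edge bins see fewer close partners), and the
coverage-product allocation within a stratum then misassigns expected mass
— pairs near chromosome ends can be called without planted signal. This is
inherent to the coverage × distance background; the calibration analysis is
therefore run on a distance-flat, structure-free simulation where every
tested pair genuinely shares one expected count and miscalibration is
attributable to the test itself, not to the discrete binomial tail at tiny
expected counts or to the edge geometry. Under that condition the raw
p < 0.05 rate is 5% (mildly conservative from discreteness) and BH makes
essentially no calls.

Feature enrichment counts calls joining a set-A bin to a set-B bin;
expected counts come from circular rotations (default 100, seeded) of the
set-B labels within each chromosome. Rotation rather than shuffling
preserves the feature's own clustering along the genome, and it preserves
per-chromosome label counts exactly, so setting B to all bins gives an
enrichment ratio of exactly zero. Gene-set clustering is the same statistic
with both ends required in the set's TSS bins and self-pairs excluded. The
significance is a Wilcoxon signed-rank over per-chromosome
(observed − expected) pairs — a documented choice among several plausible
pairings; it needs several chromosomes to have any resolution (the smallest
two-sided p with 6 all-positive chromosomes is ~0.03), which is why the
enrichment analyses and their tests run on 8-chromosome simulations. The
rotation-based expected absorbs spatially unstructured background calls,
including the edge-bias calls described above.

## Decile selections and metagene profiles

Significant genes are ranked by log2((FPKM₂+1)/(FPKM₁+1)) with a stable
(fold change, gene id) sort; the top and bottom floor(fraction × n) genes
(fraction default 0.10) form the up/down selections. The +1 pseudocount
gives genes at 0 in both conditions a fold change of exactly 0, which keeps
them out of either extreme. The metagene profile takes, per gene, one TSS
(the first annotated row — per-gene rather than per-TSS averaging is a
choice), samples the compartment PC1 step function every 1 kb across ±500
kb, orients by strand (negative offsets upstream), and averages across
genes per offset; positions off the chromosome end or in undetectable bins
are dropped from the mean rather than zero-filled.

## Synthetic data generator

The generator is the package's validation instrument: it produces data with
the statistical structure the analysis assumes, with the truth recorded so
tests never re-derive it.

Contact maps: expected counts are built multiplicatively on a power-law
distance decay P(d) ∝ (d/res)^−α (α default 1.0, standard mammalian Hi-C
behaviour), times a plaid factor ((1+s) same-compartment, 1/(1+s) cross,
s ≥ 0), times a TAD factor on intra-domain pairs, times a planted fold on
designated bin pairs; trans pairs share a flat 5% of library mass. The
matrix is Poisson-sampled around the library-scaled expectation, so counts
are integer with realistic variance. Compartments alternate in blocks
(default 5 bins ≈ 2 Mb at 400 kb, megabase scale); switched bins flip label
in the non-reference conditions.

Di-tags: valid tags are placed to reproduce the contact matrix exactly
(fragments ≥ 2 apart for cis pairs, per-end cut-site distances inside the
size range, coordinate-unique), so the QC pipeline's output conserves
counts by construction; artifact tags are appended at configured per-
category rates, and exact duplicates of valid molecules at the duplicate
rate, all labelled in a truth column that the writers strip.

Expression: log2 FPKM = per-gene baseline (3 ± 1) + effect × 1[bin is A in
that condition] + Gaussian noise per condition (defaults: effect 2, noise
0.5). Gene density is three-fold higher in A bins — real A compartments are
gene dense, and a density contrast is what makes the gene-density
orientation rule informative; positions are uniform within bins. A
configurable fraction of genes (default 5%) is floored to FPKM 0 in a
random nonempty subset of conditions, exercising the zero-handling rules. A
background fraction of non-switched genes (default 30%) receives small
shifts (sd 0.3) and a significance flag so ranked selections operate on a
realistic pool; genes in switched bins are the planted up/down truth.

Everything derives from one seed through `numpy.random.SeedSequence`;
identical seeds give byte-identical outputs, which the CLI's provenance
and rerun tests rely on.

What the generator does not emulate: sequence content and mappability
(coverage varies only by Poisson noise and edge geometry, so the
detectability mask is rarely exercised by low-mappability holes),
replicate-level batch effects, genome-wide karyotype structure, distance-
dependent plaid attenuation, and zero-inflation correlated with compartment
state. Passing tests therefore establish internal correctness and
statistical calibration of the methods under their own model assumptions,
not performance on real libraries.

## Problem sizes in the validation suite

The suite and acceptance analyses run desk-scale problems chosen to give
the statistics adequate support: compartment recovery on one chromosome of
250 bins (100 Mb at 400 kb) over 20 seeds at a 10⁶ library; interaction
calibration on ~11,000 tested pairs at a mean of ~360 counts per pair,
where the discrete binomial tail is near-uniform; enrichment on 8
chromosomes of 60 bins; Wilcoxon power at 100 genes over 100 replicates and
null calibration over 400 replicates (the ±2% band is uninformative at 100).
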