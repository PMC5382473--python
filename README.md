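# hicdelta

Differential 3D genome organization and its coupling to transcription.

`hicdelta` is a Python library (with a thin CLI) for condition-comparison
Hi-C studies — the canonical case being muscle differentiation, where
proliferating myoblasts, differentiated myotubes and AraC-purified myotubes
are profiled with Hi-C and RNA-seq and the question is where the genome's
spatial organization changes and whether those changes track expression.
It is written for genomicists who have binned contact evidence (or mapped
di-tags) and per-gene FPKM tables per condition and want the full analysis
chain with explicit, testable rules at every step:

- **di-tag QC**: HiCUP-style artifact classification (dangling ends,
  internal, circularized, re-ligation, contiguous, wrong size),
  deduplication, binning into contact matrices;
- **normalization**: expected-by-distance, observed/expected, per-chromosome
  Pearson correlation matrices; replicate correlation and pooling;
- **A/B compartments**: PC1 of the correlation matrix per chromosome,
  sign-oriented by gene density, labelled A (PC1 > 0) / B (PC1 < 0);
- **differential structure**: compartment-switch classes with Wilcoxon
  expression tests; per-bin between-condition correlation of contact
  profiles, negatively correlated (r < 0) regions, TSS partition by ΔPC1
  and paired expression tests;
- **TADs**: scaled-density dynamic programming
  (s(k,l) = Σ counts / (l−k+1)^γ, maximize Σ max(s − ⟨s⟩_len, 0)) and exact
  boundary-conservation scoring;
- **significant interactions**: coverage × distance background with
  per-stratum rescaling, upper-tail binomial p, Benjamini–Hochberg FDR;
  feature/gene-set enrichment against circular rotations with signed-rank
  significance;
- **profiles**: expression-decile gene selections and strand-aware ±500 kb
  metagene PC1 profiles;
- **synthetic data**: a seeded generator with planted truth (distance decay,
  plaid compartments with switches, TAD blocks, planted pairs, expression
  coupled to compartment) that the whole test suite is built on.

## Worked example

Simulate one condition with a plaid compartment pattern and call A/B
compartments back (this is `examples/call_compartments.py`):

```python
import numpy as np
import hicdelta as hd

cfg = hd.SimulationConfig(
    n_chromosomes=2, chrom_length=40_000_000, resolution=400_000,
    plaid_strength=1.0, library_size=1_000_000, seed=0,
)
maps, truth = hd.simulate_contact_maps(cfg)
expr = hd.simulate_expression(cfg, truth)

m = maps["myoblast"]
mask = hd.detectable_mask(m)
corr = hd.correlation_matrix(hd.observed_over_expected(m), mask)
density = hd.gene_density_per_bin(expr, truth.bins, cfg.resolution)
track = hd.call_ab_compartments(corr, truth.bins, mask, density,
                                "myoblast", cfg.resolution)
det = track.detectable
print(np.mean(track.labels[det] == truth.labels[0][det]))   # -> 1.0
```

Running the full script prints

```
bins: 200 total, 200 detectable
compartments: 100 A, 100 B
planted-label recovery: 100.0%
```

— every detectable 400 kb bin received its planted compartment label: the
oriented PC1 sign separates the two plaid states perfectly at this library
depth. Comparing two conditions (`examples/switches_and_expression.py`)
classifies every jointly detectable bin and tests resident genes:

```
switch_class  n_tested        p  median_delta direction
        A->A       361 0.333206     -0.058022  decrease
        A->B        21 0.000197     -1.457789  decrease
        B->A         5 0.062500      1.585725  increase
        B->B       117 0.219961     -0.075927  decrease
```

Bins leaving the active A compartment show a strong, significant drop in
log2(FPKM+1) (median −1.46, p ≈ 2e-4); stable classes do not — the planted
structure–expression coupling, recovered end to end. The other capabilities
each have a narrative script under `examples/`.

The pipeline can also be driven from the shell on file inputs:

```bash
hicdelta all --outdir run1 --seed 3        # simulate + every stage
hicdelta compartments --config run1/pipeline_config.txt --outdir run1
```

Each stage writes plain TSV/BED/bedGraph outputs plus a provenance record
(input checksums, parameters, seed, version); reruns under a fixed seed are
byte-identical.

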