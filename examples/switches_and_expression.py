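"""Compartment switches between conditions and their expression consequences.

Calls A/B compartments in two conditions, classifies each jointly detectable
bin as A->A, A->B, B->A or B->B, and tests whether genes in switching bins
change expression in the expected direction (Wilcoxon signed-rank on
log2(FPKM+1) changes).
"""

import hicdelta as hd

cfg = hd.SimulationConfig(
    n_chromosomes=2, chrom_length=50_000_000, resolution=400_000,
    plaid_strength=1.0, library_size=1_000_000, n_switched_bins=12, seed=3,
)
maps, truth = hd.simulate_contact_maps(cfg)
expr = hd.simulate_expression(cfg, truth)
density = hd.gene_density_per_bin(expr, truth.bins, cfg.resolution)

tracks = {}
for cond in truth.conditions:
    m = maps[cond]
    mask = hd.detectable_mask(m)
    corr = hd.correlation_matrix(hd.observed_over_expected(m), mask)
    tracks[cond] = hd.call_ab_compartments(
        corr, truth.bins, mask, density, cond, cfg.resolution
    )

switches = hd.compartment_switches(tracks["myoblast"], tracks["myotube"])
print(switches["switch_class"].value_counts().to_string())
print()

tests = hd.switch_expression_test(
    switches, expr, ("myoblast", "myotube"), truth.bins, cfg.resolution
)
print(tests[["switch_class", "n_tested", "p", "median_delta", "direction"]]
      .to_string(index=False))
print()
print("Bins leaving the active A compartment (A->B) should show a negative")
print("median log2 expression change with a small p; stable classes should")
print("not. The generator plants exactly that coupling.")
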