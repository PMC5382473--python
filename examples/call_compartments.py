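"""Call A/B compartments on a simulated Hi-C map and check planted labels.

Simulates one condition with a plaid compartment pattern, runs the
normalization chain (expected-by-distance -> O/E -> correlation matrix ->
PC1 -> orientation by gene density) and compares the calls to the truth.
"""

import numpy as np

import hicdelta as hd

cfg = hd.SimulationConfig(
    n_chromosomes=2, chrom_length=40_000_000, resolution=400_000,
    plaid_strength=1.0, library_size=1_000_000, seed=0,
)
maps, truth = hd.simulate_contact_maps(cfg)
expr = hd.simulate_expression(cfg, truth)

m = maps["myoblast"]
mask = hd.detectable_mask(m)                      # coverage-based detectability
oe = hd.observed_over_expected(m)
corr = hd.correlation_matrix(oe, mask)
density = hd.gene_density_per_bin(expr, truth.bins, cfg.resolution)
track = hd.call_ab_compartments(corr, truth.bins, mask, density, "myoblast", cfg.resolution)

det = track.detectable
accuracy = np.mean(track.labels[det] == truth.labels[0][det])
n_a = (track.labels == "A").sum()
n_b = (track.labels == "B").sum()

print(f"bins: {m.n_bins} total, {det.sum()} detectable")
print(f"compartments: {n_a} A, {n_b} B")
print(f"planted-label recovery: {accuracy:.1%}")
print()
print("A bins (positive PC1) are the gene-dense, active compartment; the")
print("recovery rate says how often the eigenvector sign matched the planted")
print("plaid pattern on bins with enough coverage to call.")
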