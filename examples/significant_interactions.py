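"""Call significant interactions and measure gene-set clustering enrichment.

Plants all pairwise interactions among a designated gene set spread over 8
chromosomes, calls interactions against the coverage x distance background,
and scores the set's clustering against circular rotations of its bins.
"""

import numpy as np
import pandas as pd

import hicdelta as hd

cfg = hd.SimulationConfig(
    n_chromosomes=8, chrom_length=24_000_000, resolution=400_000,
    plaid_strength=0.0, tad_enrichment=1.0, n_planted_pairs=0,
    n_switched_bins=0, trans_mass=0.0, library_size=4_000_000,
    planted_pair_fold=8.0, seed=11,
)
truth = hd.plant_truth(cfg)

rng = np.random.default_rng(99)
nb = cfg.bins_per_chrom
set_bins, pairs = [], []
for c in range(cfg.n_chromosomes):
    local = np.sort(rng.choice(np.arange(2, nb - 2), size=4, replace=False))
    glb = c * nb + local
    set_bins.extend(glb.tolist())
    pairs.extend(
        (int(glb[a]), int(glb[b]))
        for a in range(4) for b in range(a + 1, 4) if glb[b] - glb[a] >= 2
    )
truth.planted_pairs = pairs
maps, _ = hd.simulate_contact_maps(cfg, truth)

calls = hd.call_significant_interactions(maps["myoblast"], fdr=0.05)
sig = calls[calls["significant"]]
print(f"tested pairs: {len(calls)}, significant at q<0.05: {len(sig)}")
print(f"planted pairs: {len(pairs)}")
print("(calls beyond the planted pairs reflect the coverage-product")
print(" background's edge bias under steep distance decay; the rotation-")
print(" based expected count below absorbs that background)")

genes = pd.DataFrame(
    {"gene_id": [f"g{i}" for i in range(len(set_bins))],
     "chrom": truth.bins["chrom"].iloc[set_bins].to_numpy(),
     "tss": truth.bins["start"].iloc[set_bins].to_numpy() + 1000,
     "strand": "+"}
)
er = hd.gene_set_clustering(
    sig, truth.bins, list(genes["gene_id"]), genes, cfg.resolution, seed=1
)
print(f"gene-set clustering: observed {er.observed:.0f} vs expected "
      f"{er.expected:.2f} in-set call pairs")
print(f"log2 enrichment ratio: {er.log2_ratio:.2f}  (p = {er.p:.4f})")
print()
print("A positive log2 ratio means the set's genes interact with each other")
print("through significant contacts more often than rotated placements of")
print("the same bins would — spatial clustering of the gene set.")
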