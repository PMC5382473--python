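"""Generator contracts: determinism, planted structure, count conservation."""

import numpy as np
import pytest

import hicdelta as hd


def test_identical_seeds_give_identical_outputs(small_config):
    cfg_a = hd.SimulationConfig(**{**vars(small_config), "seed": 7})
    cfg_b = hd.SimulationConfig(**{**vars(small_config), "seed": 7})
    cfg_c = hd.SimulationConfig(**{**vars(small_config), "seed": 8})
    maps_a, truth_a = hd.simulate_contact_maps(cfg_a)
    maps_b, truth_b = hd.simulate_contact_maps(cfg_b)
    maps_c, _ = hd.simulate_contact_maps(cfg_c)
    for cond in maps_a:
        assert np.array_equal(maps_a[cond].matrix, maps_b[cond].matrix)
    assert any(
        not np.array_equal(maps_a[c].matrix, maps_c[c].matrix) for c in maps_a
    )
    assert np.array_equal(truth_a.switched_bins, truth_b.switched_bins)
    expr_a = hd.simulate_expression(cfg_a, truth_a)
    expr_b = hd.simulate_expression(cfg_b, truth_b)
    assert expr_a.equals(expr_b)
    tags_a = hd.simulate_ditags(cfg_a, truth_a, maps_a["myoblast"])
    tags_b = hd.simulate_ditags(cfg_b, truth_b, maps_b["myoblast"])
    assert tags_a.equals(tags_b)


def test_structure_free_config_depends_on_distance_only():
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=12_000_000, plaid_strength=0.0,
        tad_enrichment=1.0, n_planted_pairs=0, n_switched_bins=0,
        library_size=50_000, trans_mass=0.0, seed=1,
    )
    truth = hd.plant_truth(cfg)
    E = hd.expected_contact_matrix(cfg, truth, 0)
    n = cfg.total_bins
    for d in range(1, n):
        diag = np.diagonal(E, d)
        assert np.allclose(diag, diag[0])


def test_plaid_structure_in_observed_over_expected():
    """Per-bin mean O/E is higher toward same-compartment partners for >=95% of bins."""
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=40_000_000, plaid_strength=1.0,
        tad_enrichment=1.0, n_planted_pairs=0, n_switched_bins=10,
        library_size=1_000_000, trans_mass=0.0, n_conditions=2, seed=9,
    )
    maps, truth = hd.simulate_contact_maps(cfg)
    m = maps["myoblast"]
    oe = hd.observed_over_expected(m).values
    labels = truth.labels[0]
    good = 0
    n = cfg.total_bins
    for b in range(n):
        same = labels == labels[b]
        same[b] = False
        cross = ~(labels == labels[b])
        ratio = np.nanmean(oe[b, same]) / np.nanmean(oe[b, cross])
        good += ratio > 1
    assert good / n >= 0.95


def test_decay_exponent_recovered_from_expected_profile():
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=40_000_000, plaid_strength=0.0,
        tad_enrichment=1.0, n_planted_pairs=0, n_switched_bins=0,
        library_size=1_000_000, trans_mass=0.0, decay_exponent=1.0, seed=2,
    )
    maps, _ = hd.simulate_contact_maps(cfg)
    prof = hd.expected_by_distance(maps["myoblast"])["chr1"]
    d = np.arange(1, 50)
    slope = np.polyfit(np.log(d), np.log(prof[1:50]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_ditag_count_conservation(small_config, small_sim):
    maps, truth = small_sim
    m = maps["myoblast"]
    tags = hd.simulate_ditags(small_config, truth, m)
    rmap = small_config.restriction_map()
    valid, rebinned, report = hd.qc_pipeline(
        tags, rmap, truth.bins, small_config.resolution
    )
    assert rebinned.total == m.total
    assert np.array_equal(rebinned.matrix, m.matrix)
    assert report.n_input == len(tags)


def test_artifact_rates_recovered_by_classifier():
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=8_000_000, library_size=10_000,
        duplicate_rate=0.0, artifact_rates={"re_ligation": 0.1}, seed=13,
    )
    maps, truth = hd.simulate_contact_maps(cfg)
    tags = hd.simulate_ditags(cfg, truth, maps["myoblast"])
    cat = hd.classify_ditags(tags, cfg.restriction_map(), cfg.size_range)
    frac = (cat == "re_ligation").mean()
    assert frac == pytest.approx(0.1, abs=0.02)
    assert (cat == tags["truth_category"]).all()


def test_clean_stream_is_all_valid():
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=8_000_000, library_size=5_000,
        duplicate_rate=0.0, artifact_rates={}, seed=3,
    )
    maps, truth = hd.simulate_contact_maps(cfg)
    tags = hd.simulate_ditags(cfg, truth, maps["myoblast"])
    cat = hd.classify_ditags(tags, cfg.restriction_map(), cfg.size_range)
    assert (cat == "valid").all()


def test_duplicate_rate_drives_dedup_removals():
    cfg = hd.SimulationConfig(
        n_chromosomes=1, chrom_length=12_000_000, library_size=10_000,
        duplicate_rate=0.5, artifact_rates={}, seed=21,
    )
    maps, truth = hd.simulate_contact_maps(cfg)
    tags = hd.simulate_ditags(cfg, truth, maps["myoblast"])
    n = len(tags)
    canonical = hd.canonicalize(tags)
    _, removed = hd.deduplicate(canonical)
    # ~half the stream are duplicates, binomial spread around 0.5 n
    assert removed == pytest.approx(0.5 * n, rel=0.05)
    assert removed == (tags["truth_category"] == "duplicate").sum()


def test_expression_effect_shifts_a_compartment_genes(small_config, small_sim):
    cfg = hd.SimulationConfig(**{**vars(small_config), "expression_noise_sd": 0.0,
                                 "zero_expression_fraction": 0.0,
                                 "background_de_fraction": 0.0,
                                 "expression_effect": 2.0})
    _, truth = hd.simulate_contact_maps(cfg)
    expr = hd.simulate_expression(cfg, truth)
    down = expr[expr["gene_id"].isin(truth.down_gene_ids)]
    delta_log2 = np.log2(down["fpkm_myotube"]) - np.log2(down["fpkm_myoblast"])
    assert np.allclose(delta_log2, -2.0)
    up = expr[expr["gene_id"].isin(truth.up_gene_ids)]
    delta_up = np.log2(up["fpkm_myotube"]) - np.log2(up["fpkm_myoblast"])
    assert np.allclose(delta_up, 2.0)


def test_zero_effect_balances_a_and_b(small_config):
    cfg = hd.SimulationConfig(**{**vars(small_config), "expression_effect": 0.0,
                                 "zero_expression_fraction": 0.0, "seed": 5})
    _, truth = hd.simulate_contact_maps(cfg)
    expr = hd.simulate_expression(cfg, truth)
    from hicdelta.genome import bins_of_positions

    gene_bins = bins_of_positions(
        truth.bins, cfg.resolution, expr["chrom"].to_numpy(), expr["tss"].to_numpy()
    )
    is_a = truth.labels[0][gene_bins] == "A"
    la = np.log2(expr["fpkm_myoblast"].to_numpy()[is_a] + 1)
    lb = np.log2(expr["fpkm_myoblast"].to_numpy()[~is_a] + 1)
    assert abs(la.mean() - lb.mean()) < 0.5


def test_config_validation_errors():
    with pytest.raises(ValueError, match="library"):
        hd.SimulationConfig(library_size=0)
    with pytest.raises(ValueError, match="divide"):
        hd.SimulationConfig(chrom_length=1_000_001)
    with pytest.raises(ValueError, match="rate"):
        hd.SimulationConfig(duplicate_rate=1.5)
    with pytest.raises(ValueError, match="sum"):
        hd.SimulationConfig(artifact_rates={"re_ligation": 0.6, "wrong_size": 0.6})
    with pytest.raises(ValueError, match="noise"):
        hd.SimulationConfig(expression_noise_sd=-1.0)
    with pytest.raises(ValueError, match="switched"):
        hd.SimulationConfig(
            n_chromosomes=1, chrom_length=2_000_000, n_switched_bins=100
        )


def test_truth_invariants(small_sim):
    _, truth = small_sim
    for b in truth.switched_bins:
        assert truth.labels[0][b] != truth.labels[1][b]
    by_chrom = {}
    for chrom, s, e in truth.tad_intervals:
        assert e >= s
        for s2, e2 in by_chrom.get(chrom, []):
            assert e < s2 or s > e2
        by_chrom.setdefault(chrom, []).append((s, e))
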