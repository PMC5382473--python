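"""Switch detection, negatively correlated regions, expression tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hicdelta as hd
from hicdelta.compartments import call_compartments
from hicdelta.genome import make_bin_table
from hicdelta.stats import signed_rank_test


def _bins(n, chrom="chr1"):
    return make_bin_table({chrom: n * 400_000}, 400_000)


def _track(labels, bins, pc1=None):
    labels = np.asarray(labels, dtype=object)
    det = labels != "NA"
    if pc1 is None:
        pc1 = np.where(labels == "A", 0.5, -0.5).astype(float)
        pc1[~det] = np.nan
    return call_compartments(pc1, det, bins, "x", 400_000)


# --- compartment switches --------------------------------------------------

def test_identical_tracks_have_no_switches():
    bins = _bins(6)
    t = _track(["A", "A", "B", "B", "A", "NA"], bins)
    sw = hd.compartment_switches(t, t)
    assert (sw["switch_class"].isin(["A->A", "B->B"])).all()
    assert len(sw) == 5  # NA bin excluded


def test_all_a_to_all_b():
    bins = _bins(4)
    sw = hd.compartment_switches(_track(["A"] * 4, bins), _track(["B"] * 4, bins))
    assert (sw["switch_class"] == "A->B").all() and len(sw) == 4


def test_switch_partition_counts():
    bins = _bins(8)
    t1 = _track(["A", "A", "B", "B", "A", "B", "NA", "A"], bins)
    t2 = _track(["A", "B", "B", "A", "A", "B", "A", "NA"], bins)
    sw = hd.compartment_switches(t1, t2)
    both = 6  # bins detectable in both
    assert sw["switch_class"].value_counts().sum() == both


def test_planted_switches_recovered_noise_free(small_config):
    """With strong plaid, exactly the planted switched bins change labels."""
    cfg = hd.SimulationConfig(
        **{**vars(small_config), "plaid_strength": 2.0, "library_size": 1_000_000,
           "tad_enrichment": 1.0, "n_planted_pairs": 0, "seed": 17}
    )
    maps, truth = hd.simulate_contact_maps(cfg)
    expr = hd.simulate_expression(cfg, truth)
    gd = hd.gene_density_per_bin(expr, truth.bins, cfg.resolution)
    tracks = []
    for cond in truth.conditions:
        m = maps[cond]
        mask = hd.detectable_mask(m)
        corr = hd.correlation_matrix(hd.observed_over_expected(m), mask)
        tracks.append(
            hd.call_ab_compartments(corr, truth.bins, mask, gd, cond, cfg.resolution)
        )
    sw = hd.compartment_switches(tracks[0], tracks[1])
    flagged = set(sw.index[sw["switch_class"].isin(["A->B", "B->A"])])
    assert flagged == set(truth.switched_bins)


# --- switch expression test ------------------------------------------------

def _expr_frame(tss, fpkm1, fpkm2, chrom="chr1"):
    n = len(tss)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "tss": tss,
            "strand": "+",
            "fpkm_c1": fpkm1,
            "fpkm_c2": fpkm2,
        }
    )


def test_all_zero_changes_are_untestable():
    bins = _bins(4)
    sw = hd.compartment_switches(_track(["A"] * 4, bins), _track(["B"] * 4, bins))
    expr = _expr_frame([100, 500_000, 900_000], [5.0, 2.0, 1.0], [5.0, 2.0, 1.0])
    res = hd.switch_expression_test(sw, expr, ("c1", "c2"), bins, 400_000)
    assert not res["testable"].any()


def test_switch_expression_detects_planted_decrease():
    bins = _bins(30)
    sw = hd.compartment_switches(_track(["A"] * 30, bins), _track(["B"] * 30, bins))
    rng = np.random.default_rng(0)
    tss = rng.integers(0, 30 * 400_000, size=60)
    f1 = 2.0 ** rng.normal(5, 1, 60)
    f2 = f1 * 2.0 ** (-2 + rng.normal(0, 0.5, 60))
    res = hd.switch_expression_test(sw, _expr_frame(tss, f1, f2), ("c1", "c2"), bins, 400_000)
    row = res[res["switch_class"] == "A->B"].iloc[0]
    assert row["p"] < 0.001 and row["median_delta"] < 0


# --- Wilcoxon against exact sign-flip enumeration --------------------------

def exact_signflip_p(diffs):
    """Exact two-sided one-sample Wilcoxon p by enumerating all sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2.0**n


@pytest.mark.parametrize("seed", range(25))
def test_wilcoxon_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    d = rng.normal(0.3, 1.0, n)
    res = signed_rank_test(d)
    assert res.p == pytest.approx(exact_signflip_p(d), abs=1e-12)


# --- correlation diff and negatively correlated regions --------------------

def test_correlation_diff_identical_conditions_is_one(small_sim):
    maps, _ = small_sim
    m = maps["myoblast"]
    corr = hd.correlation_matrix(hd.observed_over_expected(m), hd.detectable_mask(m))
    r = hd.correlation_diff(corr, corr, m.bins)
    defined = ~np.isnan(r)
    assert defined.any()
    assert np.allclose(r[defined], 1.0)


def test_correlation_diff_reflected_profile_is_minus_one():
    n = 10
    bins = _bins(n)
    rng = np.random.default_rng(3)
    c1 = rng.random((n, n))
    c1 = (c1 + c1.T) / 2
    np.fill_diagonal(c1, 1.0)
    c2 = c1.copy()
    i = 4
    c2[i, :] = 2 * c1[i, :].mean() - c1[i, :]
    c2[:, i] = c2[i, :]
    r = hd.correlation_diff(c1, c2, bins)
    # direct oracle on row i excluding column i
    keep = np.ones(n, dtype=bool)
    keep[i] = False
    oracle = np.corrcoef(c1[i, keep], c2[i, keep])[0, 1]
    assert r[i] == pytest.approx(oracle, abs=1e-12)
    assert r[i] < -0.9


def test_independent_profiles_correlate_near_zero():
    n = 40
    bins = _bins(n)
    rng = np.random.default_rng(11)
    c1 = rng.normal(size=(n, n))
    c2 = rng.normal(size=(n, n))
    r = hd.correlation_diff(c1, c2, bins)
    assert abs(np.nanmean(r)) < 0.1


def test_negcorr_regions_empty_when_all_nonnegative():
    bins = _bins(5)
    r = np.array([0.5, 0.0, 0.2, np.nan, 0.9])
    assert len(hd.find_negcorr_regions(r, bins)) == 0


def test_negcorr_single_bin_region():
    bins = _bins(5)
    r = np.array([0.5, -0.1, 0.2, 0.3, 0.9])
    regions = hd.find_negcorr_regions(r, bins)
    assert len(regions) == 1
    assert regions["bin_lo"].iloc[0] == 1 and regions["bin_hi"].iloc[0] == 1
    assert regions["n_bins"].iloc[0] == 1


def test_negcorr_run_detection_matches_runlength_oracle():
    bins = _bins(10)
    r = np.array([0.1, 0.2, 0.3, 0.1, 0.2, -0.1, -0.2, -0.3, 0.4, 0.5])
    regions = hd.find_negcorr_regions(r, bins)
    assert len(regions) == 1
    assert (regions["bin_lo"].iloc[0], regions["bin_hi"].iloc[0]) == (5, 7)


def test_negcorr_regions_do_not_cross_chromosomes():
    bins = make_bin_table({"chr1": 2 * 400_000, "chr2": 2 * 400_000}, 400_000)
    r = np.array([-0.1, -0.2, -0.3, -0.4])
    regions = hd.find_negcorr_regions(r, bins)
    assert len(regions) == 2
    assert list(regions["chrom"]) == ["chr1", "chr2"]


# --- TSS partition and paired test -----------------------------------------

def test_tss_partition_fixture_199_tss_90_genes():
    """Synthetic fixture shaped like a negatively correlated region analysis:
    199 TSSs with reduced PC1 mapping onto 90 distinct genes."""
    n = 20
    bins = _bins(n)
    regions = pd.DataFrame(
        [{"chrom": "chr1", "bin_lo": 2, "bin_hi": 7, "start": 800_000,
          "end": 3_200_000, "n_bins": 6, "mean_r": -0.5}]
    )
    rng = np.random.default_rng(42)
    tss = rng.integers(800_000, 3_200_000, size=199)
    gene_ids = [f"gene_{i % 90}" for i in range(199)]  # 199 TSSs -> 90 genes
    expr = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": "chr1", "tss": tss, "strand": "+",
         "fpkm_c1": 1.0, "fpkm_c2": 1.0}
    )
    pc1_a = np.full(n, 0.5)
    pc1_b = np.full(n, 0.5)
    pc1_b[2:8] = -0.5  # every region bin decreases
    dec, inc = hd.tss_pc1_partition(regions, expr, pc1_a, pc1_b, bins, 400_000)
    assert dec.n_tss == 199 and len(dec.gene_ids) == 90
    assert inc.n_tss == 0 and len(inc.gene_ids) == 0


def test_tss_partition_zero_delta_excluded_and_boundary_convention():
    bins = _bins(4)
    regions = pd.DataFrame(
        [{"chrom": "chr1", "bin_lo": 0, "bin_hi": 2, "start": 0,
          "end": 1_200_000, "n_bins": 3, "mean_r": -0.1}]
    )
    # TSS exactly on the bin-1/bin-2 boundary belongs to bin 2 (floor rule)
    expr = pd.DataFrame(
        {"gene_id": ["g0", "g1", "g2"], "chrom": "chr1",
         "tss": [100, 800_000, 500_000], "strand": "+",
         "fpkm_c1": 1.0, "fpkm_c2": 1.0}
    )
    pc1_a = np.array([0.5, 0.5, 0.5, 0.5])
    pc1_b = np.array([0.5, 0.1, 0.9, 0.5])  # bin0 delta=0, bin1 down, bin2 up
    dec, inc = hd.tss_pc1_partition(regions, expr, pc1_a, pc1_b, bins, 400_000)
    assert dec.gene_ids == ["g2"]   # tss 500000 -> bin 1 (delta < 0)
    assert inc.gene_ids == ["g1"]   # tss 800000 -> bin 2 (delta > 0)


def test_no_tss_in_regions_gives_empty_groups():
    bins = _bins(4)
    regions = pd.DataFrame(
        [{"chrom": "chr1", "bin_lo": 3, "bin_hi": 3, "start": 1_200_000,
          "end": 1_600_000, "n_bins": 1, "mean_r": -0.2}]
    )
    expr = _expr_frame([10, 20], [1.0, 2.0], [1.0, 2.0])
    dec, inc = hd.tss_pc1_partition(
        regions, expr, np.zeros(4), np.ones(4), bins, 400_000
    )
    assert dec.n_tss == 0 and inc.n_tss == 0


def test_paired_test_zero_handling():
    # (0, 0) pair excluded; (0, 5) pair included
    expr = _expr_frame([1, 2, 3, 4], [0.0, 0.0, 3.0, 1.0], [0.0, 5.0, 4.0, 0.5])
    res = hd.paired_expression_test(["g0", "g1", "g2", "g3"], expr, ("c1", "c2"))
    assert res.n == 3  # g0 dropped, g1 kept


def test_paired_test_all_equal_pairs_untestable():
    expr = _expr_frame([1, 2, 3], [2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
    res = hd.paired_expression_test(["g0", "g1", "g2"], expr, ("c1", "c2"))
    assert not res.testable


def test_paired_test_detects_planted_halving():
    rng = np.random.default_rng(8)
    f1 = 2.0 ** rng.normal(5, 1, 90)
    f2 = 0.5 * f1 * 2.0 ** rng.normal(0, 0.2, 90)
    expr = _expr_frame(np.arange(90), f1, f2)
    res = hd.paired_expression_test([f"g{i}" for i in range(90)], expr, ("c1", "c2"))
    assert res.p < 0.001 and res.direction == "decrease"
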