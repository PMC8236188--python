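import numpy as np
import pytest
from scipy.stats import spearmanr

from maplink.calls import MaplinkError
from maplink.linkage import (
    GeneticMap,
    LinkageGroup,
    MappingFunction,
    _class_prob_stack,
    assign_chromosomes,
    build_map,
    compare_maps,
    em_recombination,
    estimate_r,
    f2_joint_class_probs,
    group_markers,
    haldane_cM,
    inverse_haldane,
    inverse_kosambi,
    kosambi_cM,
    order_markers,
    pair_counts,
    pairwise_estimates,
)
from maplink.simulate import simulate_f2_genotypes, simulate_true_map


def grid_search_r(counts, step=1e-4):
    """Independent oracle: exhaustive likelihood scan over r."""
    grid = np.arange(0.0, 0.5 + step / 2, step)
    probs = _class_prob_stack(grid)  # (n_grid, 3, 3)
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.where(probs > 0, probs, 1e-300)), 0.0)
    return float(grid[np.argmax(ll.sum(axis=(1, 2)))])


def sample_pair(r, n, rng):
    """Draw n F2 lines for a marker pair at true recombination r."""
    probs = f2_joint_class_probs(r).ravel()
    cells = rng.choice(9, size=n, p=probs)
    return (cells // 3).astype(np.int8), (cells % 3).astype(np.int8)


# -- mapping functions -------------------------------------------------------

def test_kosambi_closed_form():
    assert kosambi_cM(0.0) == 0.0
    assert kosambi_cM(0.2) == pytest.approx(21.18, abs=0.005)
    assert inverse_kosambi(21.18) == pytest.approx(0.2000, abs=5e-5)


def test_kosambi_round_trip():
    r = np.linspace(0, 0.4999, 101)
    assert np.max(np.abs(inverse_kosambi(kosambi_cM(r)) - r)) <= 1e-12


def test_haldane_round_trip_and_value():
    assert haldane_cM(0.2) == pytest.approx(-50 * np.log(0.6), rel=1e-12)
    r = np.linspace(0, 0.4999, 101)
    assert np.max(np.abs(inverse_haldane(haldane_cM(r)) - r)) <= 1e-12


def test_mapping_function_domain_errors():
    with pytest.raises(MaplinkError):
        kosambi_cM(0.5)
    with pytest.raises(MaplinkError):
        inverse_kosambi(-1.0)
    with pytest.raises(MaplinkError):
        haldane_cM(0.6)


# -- two-locus model ---------------------------------------------------------

def test_joint_probs_independence_at_half():
    table = f2_joint_class_probs(0.5)
    marg = np.array([0.25, 0.5, 0.25])
    np.testing.assert_allclose(table, np.outer(marg, marg), atol=1e-15)


def test_joint_probs_complete_linkage():
    table = f2_joint_class_probs(0.0)
    expected = np.diag([0.25, 0.5, 0.25])
    np.testing.assert_allclose(table, expected, atol=1e-15)


def test_joint_probs_closed_form_entries():
    table = f2_joint_class_probs(0.2)
    assert table[0, 0] == pytest.approx(0.16, abs=1e-12)          # (1-r)^2/4
    assert table[1, 1] == pytest.approx((0.8**2 + 0.2**2) / 2, abs=1e-12)
    assert table.sum() == pytest.approx(1.0, abs=1e-12)


def test_class_prob_stack_matches_convolution():
    for r in (0.0, 0.1, 0.33, 0.5):
        np.testing.assert_allclose(_class_prob_stack(np.array(r)),
                                   f2_joint_class_probs(r), atol=1e-14)


def test_joint_probs_match_simulation():
    tm = simulate_true_map(n_unigenes=16, snp_count_distribution={1: 1.0}, seed=0)
    tm.unigenes.loc[tm.unigenes["chromosome"] == 1, "position_cM"] = \
        [10.0, 10.0 + kosambi_cM(0.2)]
    geno = simulate_f2_genotypes(tm, n_lines=40000, seed=3)
    emp = pair_counts(geno[:, 0], geno[:, 1]) / 40000
    expected = f2_joint_class_probs(0.2)
    sd = np.sqrt(expected * (1 - expected) / 40000)
    assert (np.abs(emp - expected) < 4 * sd).all()


# -- recombination estimation ------------------------------------------------

def test_identical_vectors_estimate_zero():
    rng = np.random.default_rng(1)
    g, _ = sample_pair(0.2, 96, rng)
    pe = estimate_r(g, g)
    assert pe.r_hat == pytest.approx(0.0, abs=1e-9)
    assert pe.lod > 0


def test_unlinked_vectors_estimate_half():
    rng = np.random.default_rng(2)
    g1, _ = sample_pair(0.5, 96, rng)
    _, g2 = sample_pair(0.5, 96, rng)
    pe = estimate_r(g1, g2)
    assert pe.r_hat > 0.35
    assert pe.lod < 3


def test_estimator_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(20):
        g1, g2 = sample_pair(rng.uniform(0.02, 0.45), 96, rng)
        a, b = estimate_r(g1, g2), estimate_r(g2, g1)
        assert a.r_hat == pytest.approx(b.r_hat, abs=1e-12)
        assert a.lod == pytest.approx(b.lod, abs=1e-9)


def test_em_agrees_with_grid_oracle_large_n():
    rng = np.random.default_rng(4)
    g1, g2 = sample_pair(0.2, 10_000, rng)
    counts = pair_counts(g1, g2)
    assert abs(float(em_recombination(counts)) - grid_search_r(counts)) <= 1e-3


def test_missing_entries_skipped_pairwise():
    rng = np.random.default_rng(5)
    g1, g2 = sample_pair(0.1, 200, rng)
    g1m = g1.copy()
    g1m[:20] = -1
    pe = estimate_r(g1m, g2)
    assert pe.n_informative == 180
    ref = estimate_r(g1[20:], g2[20:])
    assert pe.r_hat == pytest.approx(ref.r_hat, abs=1e-12)


def test_low_information_flagged():
    pe = estimate_r(np.array([0, 1, 2], dtype=np.int8), np.array([0, 1, 2], dtype=np.int8))
    assert pe.low_confidence


def test_pairwise_matches_single_pair_path():
    rng = np.random.default_rng(6)
    g = np.vstack([sample_pair(0.15, 96, rng)[0] for _ in range(6)])
    r, lod = pairwise_estimates(g)
    for i in range(6):
        for j in range(i + 1, 6):
            pe = estimate_r(g[i], g[j])
            assert r[i, j] == pytest.approx(pe.r_hat, abs=1e-9)
            assert lod[i, j] == pytest.approx(pe.lod, abs=1e-6)
    assert np.allclose(r, r.T)


# -- grouping ----------------------------------------------------------------

def test_grouping_is_transitive_closure():
    ids = ["a", "b", "c"]
    lod = np.array([[99, 6, 1], [6, 99, 6], [1, 6, 99]], dtype=float)
    groups, singles = group_markers(lod, ids, 5)
    assert groups == [[0, 1, 2]] and singles == []


def test_grouping_all_below_threshold():
    lod = np.full((4, 4), 2.0)
    groups, singles = group_markers(lod, list("abcd"), 5)
    assert groups == [] and singles == [0, 1, 2, 3]


def test_two_simulated_chromosomes_split():
    tm = simulate_true_map(n_unigenes=160, total_cM=500, snp_count_distribution={1: 1.0}, seed=51)
    geno = simulate_f2_genotypes(tm, n_lines=96, seed=52)
    keep = tm.unigenes["chromosome"].isin([1, 2]).to_numpy()
    g = geno[:, keep].T
    ids = tm.unigenes.loc[keep, "unigene"].tolist()
    r, lod = pairwise_estimates(g)
    groups, singles = group_markers(lod, ids, 5)
    assert len(groups) == 2 and singles == []
    truth = tm.unigenes.set_index("unigene")["chromosome"]
    for grp in groups:
        assert len({truth[ids[i]] for i in grp}) == 1


# -- ordering ----------------------------------------------------------------

def test_order_triangle():
    r = np.array([[0, 0.05, 0.10], [0.05, 0, 0.05], [0.10, 0.05, 0]])
    order = order_markers([0, 1, 2], r, ["a", "b", "c"])
    assert order in ([0, 1, 2], [2, 1, 0])
    # canonical orientation: smaller terminal id first
    assert order == [0, 1, 2]


def test_order_two_markers_canonical():
    r = np.array([[0, 0.2], [0.2, 0]])
    assert order_markers([0, 1], r, ["b", "a"]) == [1, 0]


def test_order_recovery_simulated_group():
    tm = simulate_true_map(n_unigenes=400, snp_count_distribution={1: 1.0}, seed=53)
    geno = simulate_f2_genotypes(tm, n_lines=96, seed=54)
    keep = (tm.unigenes["chromosome"] == 1).to_numpy()
    g = geno[:, keep].T[:50]
    ids = tm.unigenes.loc[keep, "unigene"].tolist()[:50]
    true_pos = tm.unigenes.loc[keep, "position_cM"].to_numpy()[:50]
    r, _ = pairwise_estimates(g)
    order = order_markers(list(range(50)), r, ids)
    rho = spearmanr(np.arange(len(order)), true_pos[order]).statistic
    assert abs(rho) >= 0.99


# -- map assembly ------------------------------------------------------------

def test_build_map_cumulative_positions():
    r = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.2], [0.5, 0.2, 0.0]])
    gmap = build_map([[0, 1, 2]], r, ["a", "b", "c"], MappingFunction.KOSAMBI)
    # 25*ln(1.2/0.8) = 10.1366; + 25*ln(1.4/0.6) = 31.3190
    np.testing.assert_allclose(gmap.groups[0].positions_cM, [0, 10.1366, 31.3190], atol=0.005)
    assert gmap.total_cM == pytest.approx(sum(
        kosambi_cM(x) for x in gmap.groups[0].adjacent_r), abs=1e-9)


def test_build_map_singleton_group():
    gmap = build_map([[0]], np.zeros((1, 1)), ["a"])
    assert gmap.groups[0].length_cM == 0.0
    assert gmap.groups[0].adjacent_r == []


def test_adjacent_half_is_capped_and_flagged():
    r = np.array([[0.0, 0.5], [0.5, 0.0]])
    gmap = build_map([[0, 1]], r, ["a", "b"])
    assert gmap.groups[0].capped_intervals == [0]
    assert gmap.groups[0].length_cM == pytest.approx(kosambi_cM(0.49), abs=1e-9)


# -- chromosome labels -------------------------------------------------------

def _toy_map(markers_per_group):
    groups = [LinkageGroup(ms, [0.1] * (len(ms) - 1), list(np.arange(len(ms)) * 10.0))
              for ms in markers_per_group]
    return GeneticMap(groups, MappingFunction.KOSAMBI)


def test_majority_label_and_conflicts():
    gmap = _toy_map([["a", "b", "c"], ["d", "e", "f"], ["g"]])
    report = assign_chromosomes(gmap, {"a": 2, "b": 2, "c": 2, "d": 2, "e": 2, "f": 5})
    assert gmap.groups[0].chromosome == 2 and gmap.groups[0].conflicts == 0
    assert gmap.groups[1].chromosome == 2 and gmap.groups[1].conflicts == 1
    assert gmap.groups[2].chromosome is None
    assert report.loc[2, "note"] == "no anchored member"


def test_majority_tie_unlabeled():
    gmap = _toy_map([["a", "b"]])
    report = assign_chromosomes(gmap, {"a": 1, "b": 3})
    assert gmap.groups[0].chromosome is None
    assert report.loc[0, "note"] == "majority tie"


# -- map comparison ----------------------------------------------------------

def test_compare_identical_maps():
    gmap = _toy_map([["a", "b", "c", "d"]])
    report = compare_maps(gmap, gmap)
    assert bool(report.loc[0, "co_grouped"])
    assert report.loc[0, "rho_abs"] == pytest.approx(1.0)


def test_compare_reversed_group_orientation():
    map_a = _toy_map([["a", "b", "c", "d"]])
    map_b = _toy_map([["d", "c", "b", "a"]])
    report = compare_maps(map_a, map_b)
    assert report.loc[0, "rho_abs"] == pytest.approx(1.0)
    assert report.loc[0, "orientation"] == -1


def test_compare_too_few_shared_markers():
    map_a = _toy_map([["a", "b", "c"]])
    map_b = _toy_map([["a", "x", "y"]])
    report = compare_maps(map_a, map_b)
    assert report.loc[0, "n_shared"] == 1
    assert np.isnan(report.loc[0, "rho_abs"])


def test_compare_independent_samples_of_same_truth():
    tm = simulate_true_map(n_unigenes=160, snp_count_distribution={1: 1.0}, seed=55)
    ids = tm.unigenes["unigene"].tolist()
    maps = []
    for seed in (56, 57):
        geno = simulate_f2_genotypes(tm, n_lines=96, seed=seed)
        r, lod = pairwise_estimates(geno.T)
        groups, _ = group_markers(lod, ids, 5)
        ordered = [order_markers(g, r, ids) for g in groups]
        maps.append(build_map(ordered, r, ids))
    report = compare_maps(maps[0], maps[1])
    assert report["co_grouped"].all()
    assert report["rho_abs"].median() >= 0.95
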