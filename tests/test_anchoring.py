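import itertools

import numpy as np
import pytest

from maplink.anchoring import (
    AnchorStatus,
    SitePattern,
    anchor_all,
    anchor_unigene,
    classify_site,
    filter_mal_sites,
)
from maplink.calls import MaplinkError, Thresholds
from maplink.simulate import ErrorModel, simulate_mal_panel, simulate_true_map

from conftest import A, B, H, M, make_mal_panel


def pat(het_mals, position=1, min_depth=10, has_missing=False, unigene="u"):
    return SitePattern(unigene, position, frozenset(het_mals), True, True,
                       has_missing, min_depth)


# -- filtering ---------------------------------------------------------------

def test_filter_drops_low_depth_site_first():
    panel = make_mal_panel([("u1", 1, [B] * 8, [3, 10, 10, 10, 10, 10, 10, 10])])
    retained, dropped = filter_mal_sites(panel, Thresholds())
    assert retained == [] and dropped == {"depth": 1}


def test_filter_drops_bad_parental_pattern():
    # DHA heterozygous: not a clean interspecific SNP
    panel = make_mal_panel([("u1", 1, [B] * 8, None)], parent_calls=[(B, H)])
    retained, dropped = filter_mal_sites(panel, Thresholds())
    assert retained == [] and dropped == {"parental_pattern": 1}


def test_filter_retains_clean_site():
    calls = [B, B, H, B, B, B, B, B]
    panel = make_mal_panel([("u1", 7, calls, None)])
    retained, dropped = filter_mal_sites(panel, Thresholds())
    assert dropped == {}
    assert len(retained) == 1
    assert retained[0].het_mals == frozenset({3})
    assert retained[0].position == 7


def test_filter_conserves_site_totals():
    site_defs = [
        ("u1", 1, [B] * 8, [3] * 8),
        ("u1", 2, [B, H] + [B] * 6, None),
        ("u2", 1, [H] * 8, None),
    ]
    panel = make_mal_panel(site_defs, parent_calls=[(B, A), (B, H), (B, A)])
    retained, dropped = filter_mal_sites(panel, Thresholds())
    assert len(retained) + sum(dropped.values()) == panel.n_sites


# -- site classification -----------------------------------------------------

def brute_force_classify(mal_calls):
    """Independent oracle: enumerate the defining rule directly on the
    8-tuple of MAL calls — the carrier chromosome is the unique
    heterozygous MAL; anything else gives no assignment."""
    het = [c + 1 for c in range(8) if mal_calls[c] == H]
    if any(v == M for v in mal_calls):
        return None
    return het[0] if len(het) == 1 else None


def to_pattern(mal_calls):
    return pat([c + 1 for c in range(8) if mal_calls[c] == H],
               has_missing=any(v == M for v in mal_calls))


@pytest.mark.parametrize("calls,expected", [
    ((B, B, B, B, H, B, B, B), 5),
    ((B, B, H, B, B, B, H, B), None),
    ((B,) * 8, None),
    ((H,) * 8, None),
])
def test_classify_site_examples(calls, expected):
    assert classify_site(to_pattern(calls)) == expected


def test_classify_site_agrees_with_enumeration_sample():
    """Spot-check oracle equivalence on a random sample of call vectors
    (the exhaustive 3^8 sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        calls = tuple(rng.choice([A, H, B], size=8))
        assert classify_site(to_pattern(calls)) == brute_force_classify(calls)


# -- unigene aggregation -----------------------------------------------------

def test_multi_consistent():
    res = anchor_unigene("u", [pat({2}, 1), pat({2}, 5), pat({2}, 9)])
    assert (res.chromosome, res.status) == (2, AnchorStatus.MULTI_CONSISTENT)


def test_one_snp():
    res = anchor_unigene("u", [pat({7}, 3)])
    assert (res.chromosome, res.status) == (7, AnchorStatus.ONE_SNP)
    assert res.n_sites_used == 1


def test_representative_resolves_ambiguity():
    res = anchor_unigene("u", [pat({3}, 10, min_depth=6), pat({3, 7}, 2)])
    assert (res.chromosome, res.status) == (3, AnchorStatus.REPRESENTATIVE)
    assert res.representative_site == 10
    assert res.n_ambiguous_sites == 1


def test_representative_site_prefers_depth_then_position():
    sites = [pat({3}, 10, min_depth=5), pat({3}, 4, min_depth=9),
             pat({3}, 2, min_depth=9), pat({3, 4}, 1)]
    res = anchor_unigene("u", sites)
    assert res.representative_site == 2  # highest min depth, then smallest position


def test_conflicting_clean_sites_unassigned():
    res = anchor_unigene("u", [pat({1}, 1), pat({4}, 2)])
    assert res.status is AnchorStatus.UNASSIGNED and res.chromosome is None


def test_only_ambiguous_sites_unassigned():
    res = anchor_unigene("u", [pat({}, 1), pat({2, 5}, 2)])
    assert res.status is AnchorStatus.UNASSIGNED


def test_empty_site_list_errors():
    with pytest.raises(MaplinkError):
        anchor_unigene("u", [])


def test_anchoring_permutation_invariant():
    sites = [pat({5}, 1, min_depth=4), pat({5, 2}, 8), pat({5}, 12, min_depth=8)]
    results = {tuple((r.chromosome, r.status, r.representative_site)
                     for r in [anchor_unigene("u", list(perm))])
               for perm in itertools.permutations(sites)}
    assert len(results) == 1


# -- whole-panel runs --------------------------------------------------------

def test_anchor_all_noise_free_recovers_truth():
    tm = simulate_true_map(n_unigenes=120, seed=31)
    em = ErrorModel(mean_depth=40, mal_spurious_het_rate=0.0, mal_dropout_rate=0.0)
    panel = simulate_mal_panel(tm, em, seed=32)
    results, summary, _ = anchor_all(panel)
    truth = tm.chromosome_of()
    assert all(r.chromosome == truth[r.unigene_id] for r in results)
    assert all(r.status in (AnchorStatus.ONE_SNP, AnchorStatus.MULTI_CONSISTENT)
               for r in results)


def test_anchor_accuracy_degrades_with_noise():
    tm = simulate_true_map(n_unigenes=300, seed=33)
    truth = tm.chromosome_of()
    accs = []
    for noise in (0.0, 0.1, 0.4):
        em = ErrorModel(mean_depth=40, mal_spurious_het_rate=noise,
                        mal_dropout_rate=noise)
        panel = simulate_mal_panel(tm, em, seed=34)
        results, _, _ = anchor_all(panel)
        assigned = [r for r in results if r.chromosome is not None]
        accs.append(np.mean([truth[r.unigene_id] == r.chromosome for r in assigned]))
    assert accs[0] == 1.0
    assert accs[0] >= accs[1] >= accs[2] - 1e-12


def test_unigene_with_all_low_depth_sites_absent():
    panel = make_mal_panel([
        ("u1", 1, [B, B, H, B, B, B, B, B], [3] * 8),
        ("u2", 1, [B, B, B, H, B, B, B, B], None),
    ])
    results, _, dropped = anchor_all(panel)
    assert [r.unigene_id for r in results] == ["u2"]
    assert dropped["depth"] == 1


def test_summary_rows_sum_to_totals():
    tm = simulate_true_map(n_unigenes=200, seed=35)
    panel = simulate_mal_panel(tm, ErrorModel(mean_depth=30, mal_spurious_het_rate=0.1,
                                              mal_dropout_rate=0.05), seed=36)
    results, summary, _ = anchor_all(panel)
    chr_cols = [f"chr{c}" for c in range(1, 9)]
    for row in ("MULTI_CONSISTENT", "REPRESENTATIVE", "ONE_SNP"):
        assert summary.loc[row, chr_cols].sum() == summary.loc[row, "Total"]
    n_assigned = sum(r.chromosome is not None for r in results)
    assert summary.loc["Total_assigned", "Total"] == n_assigned
    assert summary.loc["UNASSIGNED", "Total"] == len(results) - n_assigned
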