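"""Sawyer fragment statistic, permutation test, evidence integration."""

import numpy as np
import pandas as pd
import pytest

from paralogy.geneconv import (
    SawyerParams,
    _max_subarray,
    _ruzzo_tompa,
    integrate,
    load_external_regions,
    polymorphic_sites,
    sawyer_fragments,
    sawyer_pvalue,
)
from paralogy.msa import Msa
from paralogy.simulate import make_paper_like_family


def _msa(rows, labels=None):
    labels = labels or [f"s{i+1}" for i in range(len(rows))]
    return Msa(labels, rows, [], {l: "X" for l in labels})


def test_identical_group_has_no_polymorphic_sites():
    msa = _msa(["ACGT", "ACGT", "ACGT"])
    assert len(polymorphic_sites(msa, msa.labels)) == 0


def test_polymorphic_sites_hand_inspection():
    msa = _msa(["ACGTACGTACGT",
                "ACGAACGTACGT",
                "ACGTACGTAGGT",
                "ACGTACGTACGT",
                ])
    assert list(polymorphic_sites(msa, msa.labels)) == [3, 9]


def test_polymorphic_sites_match_naive_scan():
    rng = np.random.default_rng(4)
    rows = ["".join(rng.choice(list("ACGT-"), 400, p=[.24, .24, .24, .24, .04]))
            for _ in range(5)]
    msa = _msa(rows)
    got = set(polymorphic_sites(msa, msa.labels))
    naive = set()
    for j in range(msa.length):
        col = [r[j] for r in rows]
        if any(c not in "ACGT" for c in col):
            continue
        if len(set(col)) >= 2:
            naive.add(j)
    assert got == naive


def test_ruzzo_tompa_finds_maximal_segments():
    walk = np.array([1.0, 1, -5, 1, 1, 1, -1, 1, -5, 1])
    segs = _ruzzo_tompa(walk)
    scores = sorted(s for _, _, s in segs)
    assert max(scores) == 3.0
    assert _max_subarray(walk) == 3.0


def test_pure_matching_run_scores_its_length():
    # pair identical at 10 consecutive polymorphic sites, mismatched elsewhere
    a = "A" * 10 + "C" * 10
    b = "A" * 10 + "G" * 10
    c = "T" * 10 + "C" * 5 + "G" * 5
    msa = _msa([a, b, c])
    sites = polymorphic_sites(msa, msa.labels)
    frags = sawyer_fragments(msa, ("s1", "s2"), sites,
                             SawyerParams(min_frag_score=2))
    assert len(frags) == 1
    assert frags.score.iloc[0] == pytest.approx(10.0)
    assert frags.aln_start.iloc[0] == 0 and frags.aln_end.iloc[0] == 10


def test_min_polymorphisms_threshold_filters_single_matches():
    # no two consecutive matches anywhere
    a = "ACACACAC"
    b = "AGAGAGAG"
    c = "TTTTTTTT"
    msa = _msa([a, b, c])
    sites = polymorphic_sites(msa, msa.labels)
    params = SawyerParams(min_polymorphisms=2, min_frag_score=2)
    frags = sawyer_fragments(msa, ("s1", "s2"), sites, params)
    assert len(frags) == 0


def test_fragments_invariant_to_monomorphic_column_insertion():
    rng = np.random.default_rng(9)
    rows = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(4)]
    msa = _msa(rows)
    sites = polymorphic_sites(msa, msa.labels)
    frags = sawyer_fragments(msa, ("s1", "s2"), sites)
    # splice a monomorphic block into the middle of every row
    rows2 = [r[:100] + "A" * 50 + r[100:] for r in rows]
    msa2 = _msa(rows2)
    sites2 = polymorphic_sites(msa2, msa2.labels)
    frags2 = sawyer_fragments(msa2, ("s1", "s2"), sites2)
    assert list(frags.score) == list(frags2.score)
    assert list(frags.n_sites) == list(frags2.n_sites)


def test_empty_site_list_gives_empty_fragments():
    msa = _msa(["ACGT", "ACGT", "ACGT"])
    frags = sawyer_fragments(msa, ("s1", "s2"), np.array([], dtype=int))
    assert len(frags) == 0


def test_pvalues_reproducible_under_fixed_seed():
    msa, _ = make_paper_like_family("one_conversion", 5)
    params = SawyerParams(n_permutations=200)
    p1 = sawyer_pvalue(msa, sorted(msa.labels), params, rng=42)
    p2 = sawyer_pvalue(msa, sorted(msa.labels), params, rng=42)
    pd.testing.assert_frame_equal(p1, p2)


def test_planted_tract_detected_with_small_corrected_p():
    msa, truth = make_paper_like_family("one_conversion", 3)
    pv = sawyer_pvalue(msa, sorted(msa.labels),
                       SawyerParams(n_permutations=1000), rng=0)
    row = pv[(pv.pair_a == "X_P1") & (pv.pair_b == "X_P3")].iloc[0]
    assert row.p_corrected < 0.05
    t = truth.conversions.iloc[0]
    assert row.aln_start < t.end and row.aln_end > t.start


def test_observed_statistic_uniform_on_permuted_input():
    # column-permuted input destroys clustering: the observed best score
    # should sit at a uniform percentile of its own permutation null
    from scipy.stats import kstest
    msa, _ = make_paper_like_family("no_conversion", 11)
    rng = np.random.default_rng(1)
    group = sorted(msa.labels)
    sites = polymorphic_sites(msa, group)
    from paralogy.geneconv import _null_best_scores, _pair_walk
    _, walk = _pair_walk(msa, (group[0], group[1]), sites, 1.0)
    percentiles = []
    for _ in range(200):
        shuffled = rng.permutation(walk)
        obs = _max_subarray(shuffled)
        null = _null_best_scores(shuffled, 99, rng)
        percentiles.append((null < obs - 1e-12).mean())
    assert kstest(percentiles, "uniform").pvalue > 0.01


def test_zero_permutations_rejected():
    msa, _ = make_paper_like_family("no_conversion", 1)
    with pytest.raises(ValueError, match="n_permutations"):
        sawyer_pvalue(msa, sorted(msa.labels),
                      SawyerParams(n_permutations=0), rng=0)


def test_integrate_tiers_and_uncorroborated():
    cands = pd.DataFrame([
        {"pair_a": "a", "pair_b": "b", "start": 100, "end": 500,
         "peak": 0.98, "n_windows": 10},
        {"pair_a": "c", "pair_b": "d", "start": 900, "end": 1000,
         "peak": 0.97, "n_windows": 3},
    ])
    coloc = pd.DataFrame([
        {"char_start": 200, "char_length": 3, "sharing": "a,b",
         "region_start": 100, "region_end": 500, "region_pair": "a,b",
         "corroborating": True, "orphan": False},
    ])
    sawyer = pd.DataFrame([
        {"pair_a": "e", "pair_b": "f", "score": 30.0, "p_raw": 0.001,
         "p_corrected": 0.006, "aln_start": 2000, "aln_end": 2400},
    ])
    calls, lonely = integrate(cands, coloc, sawyer)
    recent = calls[calls.tier == "recent"]
    ancient = calls[calls.tier == "ancient"]
    assert len(recent) == 1 and recent.iloc[0].pair_a == "a"
    assert "microindel" in recent.iloc[0].evidence
    assert len(ancient) == 1 and ancient.iloc[0].pair_a == "e"
    assert len(lonely) == 1 and lonely.iloc[0].pair_a == "c"


def test_integrate_merges_overlapping_calls_same_pair():
    cands = pd.DataFrame([
        {"pair_a": "a", "pair_b": "b", "start": 100, "end": 500,
         "peak": 0.98, "n_windows": 10},
        {"pair_a": "a", "pair_b": "b", "start": 400, "end": 800,
         "peak": 0.99, "n_windows": 10},
    ])
    sawyer = pd.DataFrame([
        {"pair_a": "a", "pair_b": "b", "score": 50.0, "p_raw": 0.001,
         "p_corrected": 0.004, "aln_start": 150, "aln_end": 700},
    ])
    calls, _ = integrate(cands, None, sawyer)
    assert len(calls) == 1
    row = calls.iloc[0]
    assert (row.start, row.end) == (100, 800)
    assert row.tier == "recent"


def test_external_region_import_and_evidence(tmp_path):
    path = tmp_path / "rdp.tsv"
    path.write_text("pair_a\tpair_b\tstart\tend\tmethod\tp\n"
                    "a\tb\t120\t480\tRDP\t0.01\n")
    external = load_external_regions(path)
    cands = pd.DataFrame([
        {"pair_a": "a", "pair_b": "b", "start": 100, "end": 500,
         "peak": 0.97, "n_windows": 5},
    ])
    calls, lonely = integrate(cands, None, None, external=external)
    assert len(calls) == 1 and "RDP" in calls.iloc[0].evidence
    bad = tmp_path / "bad.tsv"
    bad.write_text("pair_a\tstart\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_external_regions(bad)
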