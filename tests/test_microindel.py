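"""Micro-indel coding and binary-character parsimony."""

import numpy as np
import pytest

from paralogy.microindel import (
    MISSING,
    colocalize,
    compare_topologies,
    extract_indels,
    fitch_steps,
    to_nexus,
)
from paralogy.msa import Msa
from paralogy.simulate import SimConfig, simulate_family
from paralogy.trees import brute_force_count, tree_from_newick

from conftest import random_binary_newick
import pandas as pd


def _msa(rows, labels=None):
    labels = labels or [f"s{i+1}" for i in range(len(rows))]
    return Msa(labels, rows, [], {l: "X" for l in labels})


def test_shared_gap_coded_as_one_character():
    msa = _msa(["ACGTA---AC",
                "ACGTA---AC",
                "ACGTATTTAC",
                "ACGTATTTAC"])
    mim = extract_indels(msa)
    assert mim.n_characters == 1
    assert mim.characters.iloc[0].start == 5
    assert mim.characters.iloc[0].length == 3
    assert list(mim.states[:, 0]) == [1, 1, 0, 0]
    assert bool(mim.characters.informative.iloc[0])


def test_unequal_length_overlapping_gaps_are_distinct_characters():
    msa = _msa(["ACGTA---AC",
                "ACGTA----C",
                "ACGTATTTAC"])
    mim = extract_indels(msa)
    assert mim.n_characters == 2
    # each is a singleton, hence uninformative
    assert not mim.characters.informative.any()


def test_engulfing_gap_codes_missing():
    msa = _msa(["AC---TACGT",
                "AC---TACGT",
                "A--------T",
                "ACTTTTACGT"])
    mim = extract_indels(msa, max_len=5)
    shared = mim.characters[(mim.characters.start == 2)
                            & (mim.characters.length == 3)]
    assert len(shared) == 1
    k = shared.index[0]
    assert list(mim.states[:, k]) == [1, 1, MISSING, 0]


def test_no_gaps_gives_empty_matrix():
    mim = extract_indels(_msa(["ACGT", "ACGT"]))
    assert mim.n_characters == 0


def test_runs_longer_than_cutoff_excluded():
    msa = _msa(["A" + "-" * 8 + "T", "A" + "-" * 8 + "T", "A" * 10])
    assert extract_indels(msa, max_len=5).n_characters == 0
    assert extract_indels(msa, max_len=8).n_characters == 1


@pytest.mark.parametrize("states,newick,expected", [
    ([1, 1, 0, 0], "((s1,s2),(s3,s4));", 1),
    ([1, 0, 1, 0], "((s1,s2),(s3,s4));", 2),
    ([1, 1, 1, 1], "((s1,s2),(s3,s4));", 0),
])
def test_binary_fitch_hand_examples(states, newick, expected):
    gap = "---"
    rows = [("AAA" + (gap if s else "TTT") + "AAA") for s in states]
    mim = extract_indels(_msa(rows))
    report = fitch_steps(mim, tree_from_newick(newick))
    assert report.total_steps == expected
    if expected > 1:
        assert report.per_character.homoplasic.iloc[0]


def test_missing_states_pruned_per_character():
    msa = _msa(["AC---TACGT",
                "AC---TACGT",
                "A--------T",
                "ACTTTTACGT"])
    mim = extract_indels(msa, max_len=5)
    report = fitch_steps(mim, tree_from_newick("((s1,s2),(s3,s4));"))
    shared = report.per_character[
        (report.per_character.start == 2) & (report.per_character.length == 3)
    ]
    assert int(shared.steps.iloc[0]) == 1


def test_compare_topologies_prefers_generating_tree():
    rows = ["AAA---AAA", "AAA---AAA", "AAATTTAAA", "AAATTTAAA"]
    mim = extract_indels(_msa(rows))
    reports = compare_topologies(mim, {
        "matched": tree_from_newick("((s1,s2),(s3,s4));"),
        "swapped": tree_from_newick("((s1,s3),(s2,s4));"),
    })
    assert [r.topology_id for r in reports] == ["matched", "swapped"]
    assert [r.total_steps for r in reports] == [1, 2]
    assert reports[1].delta_to_best == 1


def test_identical_topologies_equal_totals():
    rows = ["AAA---AAA", "AAA---AAA", "AAATTTAAA", "AAATTTAAA"]
    mim = extract_indels(_msa(rows))
    reports = compare_topologies(mim, {
        "a": tree_from_newick("((s1,s2),(s3,s4));"),
        "b": tree_from_newick("((s2,s1),(s4,s3));"),
    })
    assert reports[0].total_steps == reports[1].total_steps


def test_parsimony_invariant_to_rerooting():
    rng = np.random.default_rng(8)
    rows = []
    for _ in range(6):
        blocks = []
        for k in range(10):
            blocks.append("---" if rng.random() < 0.4 else "ACG")
        rows.append("AAA" + "".join(blocks) + "TTT")
    mim = extract_indels(_msa(rows))
    rooted = tree_from_newick("((s1,s2),((s3,s4),(s5,s6)));")
    rerooted = tree_from_newick("(((s1,s2),(s3,s4)),(s5,s6));")
    r1 = fitch_steps(mim, rooted)
    r2 = fitch_steps(mim, rerooted)
    assert r1.total_steps == r2.total_steps


def test_fitch_totals_equal_brute_force_on_random_matrices():
    rng = np.random.default_rng(17)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        labels = [f"s{i+1}" for i in range(n)]
        tree = tree_from_newick(random_binary_newick(labels, rng))
        rows = []
        for _ in range(n):
            blocks = ["---" if rng.random() < 0.5 else "ACG"
                      for _ in range(8)]
            rows.append("A" + "".join(blocks) + "T")
        msa = _msa(rows, labels)
        mim = extract_indels(msa)
        report = fitch_steps(mim, tree)
        for k in range(mim.n_characters):
            states = {
                l: (None if mim.states[i, k] == MISSING
                    else int(mim.states[i, k]))
                for i, l in enumerate(labels)
            }
            assert report.per_character.steps.iloc[k] == \
                brute_force_count(tree, states)


def test_simulated_shared_indels_recovered():
    cfg = SimConfig(
        species_newick="((A:20000000,B:20000000):20000000,"
                       "(C:20000000,D:20000000):20000000);",
        length=12000, subs_rate=1.0e-9,
        indel_rate=8e-11, indel_mean_len=4.0, seed=21)
    msa, truth = simulate_family(cfg)
    mim = extract_indels(msa)
    found = {(int(r.start), int(r.length))
             for r in mim.characters.itertuples()}
    shared = truth.indels[
        (truth.indels.kind == "del") & truth.indels.contiguous
        & truth.indels.lineage.map(
            lambda l: len(truth.descendants[l]) >= 2)
    ]
    planted = {(int(r.start), int(r.end - r.start))
               for r in shared.itertuples()}
    assert len(planted) >= 10
    recovered = sum(1 for p in planted if p in found)
    assert recovered >= 0.9 * len(planted)


def test_colocalize_annotates_overlap_and_orphans():
    per_char = pd.DataFrame([
        {"start": 10, "length": 3, "informative": True, "degenerate": False,
         "steps": 2, "homoplasic": True},
        {"start": 500, "length": 2, "informative": True, "degenerate": False,
         "steps": 2, "homoplasic": True},
    ])
    from paralogy.microindel import MicroIndelMatrix, ParsimonyReport
    states = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
    mim = MicroIndelMatrix(["a", "b", "c", "d"],
                           per_char[["start", "length", "informative"]]
                           .assign(n_present=2), states)
    report = ParsimonyReport("t", 4, per_char)
    regions = pd.DataFrame([
        {"pair_a": "a", "pair_b": "b", "start": 0, "end": 50, "peak": 0.99},
    ])
    out = colocalize(report, mim, regions)
    inside = out[out.char_start == 10].iloc[0]
    orphan = out[out.char_start == 500].iloc[0]
    assert inside.corroborating and not inside.orphan
    assert orphan.orphan and not orphan.corroborating


def test_nexus_export_roundtrips_through_dendropy(tmp_path):
    import dendropy
    rows = ["AAA---AAA", "AAA---AAA", "AAATTTAAA", "AAATTTAAA"]
    mim = extract_indels(_msa(rows))
    path = tmp_path / "m.nex"
    to_nexus(mim, path)
    mat = dendropy.StandardCharacterMatrix.get(path=str(path),
                                               schema="nexus")
    assert len(mat) == 4
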