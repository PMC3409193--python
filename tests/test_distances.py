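"""Distance estimation, published-matrix summaries, orthologs, NJ."""

import numpy as np
import pytest

from paralogy import datasets
from paralogy.distances import (
    DistanceMatrix,
    assign_orthologs,
    group_averages,
    neighbor_joining,
    pairwise_distance,
    per_region_nearest,
)
from paralogy.msa import Msa, Region
from paralogy.simulate import SimConfig, Duplication, simulate_family
from paralogy.trees import same_unrooted_topology, tree_from_newick


def _pair_msa(a, b):
    return Msa(["x", "y"], [a, b], [], {"x": "X", "y": "Y"})


def test_identical_sequences_zero_distance():
    dm = pairwise_distance(_pair_msa("ACGTACGT", "ACGTACGT"), model="p")
    assert dm.get("x", "y") == 0.0


def test_p_distance_hand_count():
    dm = pairwise_distance(_pair_msa("ACGT", "AGGT"), model="p")
    assert dm.get("x", "y") == pytest.approx(0.25)
    assert dm.n_sites[0, 1] == 4


def test_pairwise_gap_deletion():
    # gapped or N columns dropped for the pair: 1 mismatch over 4 sites
    dm = pairwise_distance(_pair_msa("AC-GTN", "ACCGAC"), model="p")
    assert dm.n_sites[0, 1] == 4
    assert dm.get("x", "y") == pytest.approx(0.25)


def test_no_comparable_sites_gives_nan():
    with pytest.warns(UserWarning, match="no comparable"):
        dm = pairwise_distance(_pair_msa("--AA", "TT--"), model="p")
    assert np.isnan(dm.get("x", "y"))


def test_jc_saturation_gives_nan():
    with pytest.warns(UserWarning, match="saturated"):
        dm = pairwise_distance(_pair_msa("ACGTACGT", "CAATCATA"), model="jc")
    assert np.isnan(dm.get("x", "y"))


def test_correction_ordering_p_le_jc_le_tn93():
    rng = np.random.default_rng(5)
    cfg = SimConfig(species_newick="(A:40000000,B:40000000);",
                    length=20000, subs_rate=2.0e-9, seed=9)
    msa, _ = simulate_family(cfg)
    d_p = pairwise_distance(msa, "p").d[0, 1]
    d_jc = pairwise_distance(msa, "jc").d[0, 1]
    d_k2p = pairwise_distance(msa, "k2p").d[0, 1]
    d_tn = pairwise_distance(msa, "tn93").d[0, 1]
    assert d_p <= d_jc <= d_tn + 1e-12
    assert d_jc <= d_k2p + 1e-3


def test_tn93_recovers_true_divergence_within_3_se():
    cfg = SimConfig(species_newick="(A:37500000,B:37500000);",
                    length=100000, subs_rate=2.0e-9, seed=11)
    msa, _ = simulate_family(cfg)  # true divergence 0.15
    dm = pairwise_distance(msa, model="tn93")
    d, se = dm.get("A_P1", "B_P1"), np.sqrt(dm.var[0, 1])
    assert abs(d - 0.15) < 3 * se


def test_distance_matrix_invariants():
    dm = datasets.adh1_intron_distances()
    finite = ~np.isnan(dm.d)
    assert np.allclose(dm.d[finite] - dm.d.T[finite.T], 0, atol=1e-12)
    assert np.all(np.diag(dm.d) == 0)
    assert np.nanmin(dm.d) >= 0


def test_published_matrix_group_averages_match_printed_summaries():
    dm = datasets.adh1_intron_distances()
    out = group_averages(dm, datasets.adh1_paralog_contrasts())
    expected = {
        "human_paralogs": 0.135,
        "macaque_paralogs": 0.157,
        "marmoset_paralogs": 0.172,
        "all_paralogs": 0.158,
        "ortholog_human_vs_macaque": 0.065,
        "ortholog_catarrhine_vs_marmoset": 0.129,
    }
    for name, value in expected.items():
        got = float(out[out.contrast == name]["mean"].iloc[0])
        assert got == pytest.approx(value, abs=1e-3), name


def test_group_average_single_pair_sd_is_na():
    dm = datasets.adh1_intron_distances()
    out = group_averages(dm, {"one": [("Hum_ADH1A", "Hum_ADH1B")]})
    assert out["mean"].iloc[0] == pytest.approx(0.123)
    assert np.isnan(out.sd.iloc[0])


def test_empty_contrast_reported_with_reason():
    dm = datasets.adh1_intron_distances()
    out = group_averages(dm, {"none": []})
    assert np.isnan(out["mean"].iloc[0])
    assert out.note.iloc[0] == "empty contrast"


def test_ortholog_assignment_matches_published_best_pairs():
    dm = datasets.adh1_intron_distances()
    omap = assign_orthologs(dm, datasets.adh1_species_of())
    expect = {
        "Hum_ADH1A": ("Cal_ADH1.2", 0.127),
        "Hum_ADH1B": ("Cal_ADH1.3", 0.124),
        "Hum_ADH1C": ("Cal_ADH1.4", 0.120),
    }
    t = omap.table
    for label, (partner, d) in expect.items():
        row = t[(t.label == label) & (t.partner_species == "Cal")].iloc[0]
        assert row.partner == partner
        assert row.distance == pytest.approx(d)
        assert row.margin > 0
        assert not row.ambiguous


def test_ortholog_tie_flagged_ambiguous():
    d = np.array([[0.0, 0.5, 0.1, 0.1],
                  [0.5, 0.0, 0.4, 0.3],
                  [0.1, 0.4, 0.0, 0.6],
                  [0.1, 0.3, 0.6, 0.0]])
    dm = DistanceMatrix(["X_a", "X_b", "Y_a", "Y_b"], d)
    omap = assign_orthologs(dm, {"X_a": "X", "X_b": "X",
                                 "Y_a": "Y", "Y_b": "Y"})
    row = omap.table[(omap.table.label == "X_a")].iloc[0]
    assert row.ambiguous


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5],
                  [0.3, 0.0, 0.6],
                  [0.5, 0.6, 0.0]])
    dm = DistanceMatrix(["a", "b", "c"], d)
    tree = neighbor_joining(dm)
    lengths = {l.taxon.label: l.edge.length
               for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_additive_five_taxon_tree():
    # path-length matrix of ((a:2,b:3):1,(c:1,d:4):2,e:6)
    truth = tree_from_newick("((a:2,b:3):1,(c:1,d:4):2,e:6);")
    pdm = truth.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in truth.leaf_node_iter())
    taxa = {t.label: t for t in truth.taxon_namespace}
    d = np.array([[pdm.distance(taxa[a], taxa[b]) for b in labels]
                  for a in labels])
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert same_unrooted_topology(tree, truth)
    # additive: NJ path lengths reproduce the input distances
    pdm2 = tree.phylogenetic_distance_matrix()
    taxa2 = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            assert pdm2.distance(taxa2[a], taxa2[b]) == pytest.approx(
                d[i, labels.index(b)], abs=1e-9)


def test_nj_refuses_incomplete_matrix():
    dm = datasets.adh1_intron_distances()
    with pytest.raises(ValueError, match="Mac_ADH1.2"):
        neighbor_joining(dm)


def test_nj_on_published_matrix_groups_printed_sister_pairs():
    dm = datasets.adh1_intron_distances()
    keep = [l for l in dm.labels if l not in ("Mac_ADH1.2", "Mac_ADH1.0")]
    sub = dm.submatrix(keep)
    # Mac_ADH1.0's marmoset comparisons are present; drop only what is NA
    assert sub.is_complete
    tree = neighbor_joining(sub)
    tree.encode_bipartitions()
    clades = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in tree.preorder_edge_iter() if e.head_node}
    for pair in [{"Hum_ADH1A", "Mac_ADH1.1"},
                 {"Hum_ADH1B", "Mac_ADH1.3"},
                 {"Hum_ADH1C", "Mac_ADH1.4"}]:
        assert frozenset(pair) in clades


def test_per_region_nearest_flags_synthetic_chimera():
    from paralogy.simulate import make_paper_like_family
    msa, truth = make_paper_like_family("chimeric_dup", 7)
    table, flags = per_region_nearest(msa, model="p")
    row = flags[flags.label == "A_PX"].iloc[0]
    assert row.chimera
    assert row.parent_5p == "A_P1" and row.parent_3p == "A_P3"


def test_per_region_nearest_no_flag_without_chimera():
    cfg = SimConfig(
        species_newick="(A:10000000);", root_stem=30e6, length=3000,
        regions=[(f"r{i}", 750, None) for i in range(1, 5)],
        subs_rate=2.0e-9,
        duplications=[Duplication(35e6, "P1", "P2"),
                      Duplication(30e6, "P2", "P3")],
        seed=3)
    msa, _ = simulate_family(cfg)
    _, flags = per_region_nearest(msa, model="p")
    assert not flags.chimera.any()


def test_per_region_nearest_short_region_low_confidence():
    labels = ["X_a", "X_b", "X_c"]
    rng = np.random.default_rng(0)
    core = "".join(rng.choice(list("ACGT"), 150))
    rows = [core + "ACGTA", core + "ACGTA", core[:-10] + "TTTTTTTTTT" + "ACGTT"]
    msa = Msa(labels, rows, [Region("big", 0, 150), Region("tiny", 150, 155)])
    table, flags = per_region_nearest(msa, model="p")
    assert table[table.region == "tiny"].low_confidence.all()
    assert not flags.chimera.any()
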