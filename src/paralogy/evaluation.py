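"""Benchmark routines: each re-runs a pipeline stage on its worked example
or on simulated families with known truth and measures the outcome.

These back both the acceptance test suite and ``scripts/acceptance.py``;
every quantity is recomputed from scratch at call time.
"""

from __future__ import annotations

import warnings

import numpy as np

from paralogy import datasets
from paralogy.clock import ClockParams, trex_date
from paralogy.distances import (
    DistanceMatrix,
    assign_orthologs,
    group_averages,
    neighbor_joining,
    pairwise_distance,
)
from paralogy.geneconv import SawyerParams, integrate, sawyer_pvalue
from paralogy.microindel import compare_topologies, extract_indels
from paralogy.msa import Msa
from paralogy.similarity import ScanParams, candidate_regions, \
    windowed_similarity
from paralogy.simulate import SimConfig, make_paper_like_family, \
    simulate_family, simulate_silent_pair
from paralogy.trees import brute_force_count, fitch_count, \
    same_unrooted_topology, tree_from_newick

__all__ = [
    "published_matrix_summaries",
    "published_ortholog_assignment",
    "fitch_oracle_agreement",
    "indel_topology_contrast",
    "nj_additive_recovery",
    "nj_simulated_recovery",
    "trex_recovery",
    "sawyer_size",
    "conversion_power",
]


def published_matrix_summaries() -> dict[str, float]:
    """Group averages of the published 12-paralog intron distance matrix."""
    dm = datasets.adh1_intron_distances()
    out = group_averages(dm, datasets.adh1_paralog_contrasts())
    return dict(zip(out.contrast, out["mean"].astype(float)))


def published_ortholog_assignment() -> dict[str, tuple[str, float, float]]:
    """Best human-marmoset partners from the published matrix."""
    dm = datasets.adh1_intron_distances()
    omap = assign_orthologs(dm, datasets.adh1_species_of())
    t = omap.table
    out = {}
    for label in ["Hum_ADH1A", "Hum_ADH1B", "Hum_ADH1C"]:
        row = t[(t.label == label) & (t.partner_species == "Cal")].iloc[0]
        out[label] = (row.partner, float(row.distance), float(row.margin))
    return out


def _random_newick(labels, rng) -> str:
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def fitch_oracle_agreement(n_characters: int, seed: int,
                           max_leaves: int = 8) -> float:
    """Fraction of random binary characters on random trees where the Fitch
    count equals the exhaustive ancestral-enumeration minimum."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_characters):
        n = int(rng.integers(4, max_leaves + 1))
        labels = [f"L{i}" for i in range(n)]
        tree = tree_from_newick(_random_newick(labels, rng))
        states = {
            l: (None if rng.random() < 0.1 else int(rng.integers(2)))
            for l in labels
        }
        if fitch_count(tree, states) == brute_force_count(tree, states):
            agree += 1
    return agree / n_characters


def indel_topology_contrast(seed: int) -> dict[str, int]:
    """Micro-indel parsimony totals of a simulated family on its true
    topology versus a branch-swapped alternative."""
    cfg = SimConfig(
        species_newick="((A:20000000,B:20000000):20000000,"
                       "(C:20000000,D:20000000):20000000);",
        length=12000, subs_rate=1.0e-9,
        indel_rate=8e-11, indel_mean_len=4.0, seed=seed)
    msa, _ = simulate_family(cfg)
    mim = extract_indels(msa).informative()
    reports = compare_topologies(mim, {
        "true": tree_from_newick("((A_P1,B_P1),(C_P1,D_P1));"),
        "swapped": tree_from_newick("((A_P1,C_P1),(B_P1,D_P1));"),
    })
    return {r.topology_id: r.total_steps for r in reports}


def nj_additive_recovery() -> bool:
    """NJ on the path-length matrix of a known tree recovers it exactly."""
    truth = tree_from_newick("(((a:2,b:3):1,(c:1,d:4):2):1,(e:3,f:2):4);")
    pdm = truth.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in truth.leaf_node_iter())
    taxa = {t.label: t for t in truth.taxon_namespace}
    d = np.array([[pdm.distance(taxa[a], taxa[b]) for b in labels]
                  for a in labels])
    tree = neighbor_joining(DistanceMatrix(labels, d))
    return same_unrooted_topology(tree, truth)


_NJ_SPECIES = ("(((A:15000000,B:15000000):10000000,"
               "(C:15000000,D:15000000):10000000):20000000,"
               "((E:15000000,F:15000000):10000000,"
               "(G:15000000,H:15000000):10000000):20000000);")
_NJ_TRUE = ("(((A_P1,B_P1),(C_P1,D_P1)),((E_P1,F_P1),(G_P1,H_P1)));")


def nj_simulated_recovery(n_replicates: int, seed: int,
                          length: int = 50000, model: str = "jc") -> float:
    """Fraction of simulated intron alignments (pairwise divergences
    0.06-0.18) whose NJ tree matches the generating topology."""
    truth = tree_from_newick(_NJ_TRUE)
    hits = 0
    for rep in range(n_replicates):
        cfg = SimConfig(species_newick=_NJ_SPECIES, length=length,
                        subs_rate=2.0e-9, seed=seed + rep)
        msa, _ = simulate_family(cfg)
        dm = pairwise_distance(msa, model=model)
        if same_unrooted_topology(neighbor_joining(dm), truth):
            hits += 1
    return hits / n_replicates


def trex_recovery(n_pairs: int, seed: int, n_sites: int = 500,
                  T_true: float = 40e6) -> dict[str, float]:
    """Median TREx date estimate over simulated silent-site pairs, as a
    relative error against the true divergence time."""
    cp = ClockParams()
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_pairs):
        f2 = simulate_silent_pair(T_true, n_sites, rate=cp.rate, p1=cp.p1,
                                  rng=rng)
        d = trex_date(f2, n_sites, cp)
        if not d.saturated:
            estimates.append(d.date)
    median = float(np.median(estimates))
    return {
        "median_date": median,
        "relative_error": abs(median - T_true) / T_true,
        "n_dated": len(estimates),
    }


def _group_scan(msa: Msa, params: ScanParams):
    tracks = []
    labels = sorted(msa.labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            tracks.append(windowed_similarity(msa, (a, b), params))
    return candidate_regions(tracks, params)


def sawyer_size(n_groups: int, seed: int, n_permutations: int = 1000
                ) -> dict[str, float]:
    """Type-I error of the fragment permutation test, and the recent-tier
    false-call rate, on conversion-free simulated paralog groups."""
    sparams = SawyerParams(n_permutations=n_permutations)
    scan = ScanParams(window=250, step=25)
    rng = np.random.default_rng(seed)
    sig_groups = 0
    false_calls = 0
    for g in range(n_groups):
        msa, _ = make_paper_like_family("no_conversion",
                                        int(rng.integers(2 ** 31)))
        group = sorted(msa.labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pv = sawyer_pvalue(msa, group, sparams, rng)
        if (pv.p_corrected < sparams.alpha).any():
            sig_groups += 1
        cands = _group_scan(msa, scan)
        calls, _ = integrate(cands, None, pv, alpha=sparams.alpha)
        if len(calls) and (calls.tier == "recent").any():
            false_calls += 1
    return {
        "type_i_rate": sig_groups / n_groups,
        "recent_false_call_rate": false_calls / n_groups,
    }


def conversion_power(n_replicates: int, seed: int,
                     n_permutations: int = 1000) -> dict[str, float]:
    """Recall and tract overlap of integrated recent-tier calls on families
    carrying one planted conversion tract."""
    sparams = SawyerParams(n_permutations=n_permutations)
    scan = ScanParams(window=250, step=25)
    rng = np.random.default_rng(seed)
    hits, jaccards = 0, []
    for rep in range(n_replicates):
        msa, truth = make_paper_like_family("one_conversion",
                                            int(rng.integers(2 ** 31)))
        tract = truth.conversions.iloc[0]
        pair = {f"X_{tract.donor}", f"X_{tract.recipient}"}
        group = sorted(msa.labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pv = sawyer_pvalue(msa, group, sparams, rng)
        cands = _group_scan(msa, scan)
        calls, _ = integrate(cands, None, pv, alpha=sparams.alpha)
        recent = calls[(calls.tier == "recent")] if len(calls) else calls
        matched = False
        for _, call in recent.iterrows():
            if {call.pair_a, call.pair_b} != pair:
                continue
            inter = (min(call.end, tract.end)
                     - max(call.start, tract.start))
            if inter <= 0:
                continue
            union = (max(call.end, tract.end)
                     - min(call.start, tract.start))
            matched = True
            jaccards.append(inter / union)
            break
        if matched:
            hits += 1
    return {
        "recall": hits / n_replicates,
        "median_jaccard": float(np.median(jaccards)) if jaccards else 0.0,
    }
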