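"""Sawyer-style gene-conversion statistics and evidence integration.

Within a group of same-species paralogs, only polymorphic columns carry
information about conversion.  For each pair, the polymorphic columns form
a +/- walk: +1 where the pair matches, -penalty where it mismatches; a
conversion tract shows up as an unusually high-scoring run.  Significance
comes from a permutation test: shuffling the polymorphic-column order
destroys linear clustering while preserving site frequencies, so the null
distribution of the best fragment score is built from shuffles of the
observed walk.  P-values are Bonferroni-corrected across pairs within the
species group.

The mismatch penalty is ``g_scale * (n_match / n_mismatch)`` for the pair,
so at the conventional g_scale = 1 the expected increment of the walk is
zero; g_scale = 0 restricts fragments to mismatch-free runs.  The constant
is configurable; exact score equality with any particular external
implementation is not guaranteed.

``integrate`` combines the evidence lines into calls: a *recent* call needs
a high-similarity candidate region plus at least one corroborating
indicator (co-localized homoplasic micro-indel, significant fragment, or an
imported external-method region); a significant fragment without a
high-similarity window becomes an *ancient* call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from paralogy.msa import Msa

__all__ = ["SawyerParams", "polymorphic_sites", "sawyer_fragments",
           "sawyer_pvalue", "integrate", "load_external_regions"]

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class SawyerParams:
    g_scale: float = 1.0
    min_frag_len: int = 1          # nt of alignment spanned
    min_polymorphisms: int = 2
    min_frag_score: float = 2.0
    max_overlap_frags: int = 1
    n_permutations: int = 1000
    alpha: float = 0.05


def polymorphic_sites(msa: Msa, group: list[str]) -> np.ndarray:
    """Columns with >=2 states among the group; columns containing a gap or
    N within the group are skipped.  Pairwise-only mode (2 sequences) is
    allowed but flagged with a warning."""
    if len(group) < 2:
        raise ValueError("group needs >=2 sequences")
    if len(group) == 2:
        warnings.warn("pairwise-only group: permutation null is weak")
    arr = msa.subset(group).array()
    good = np.isin(arr, _BASES).all(axis=0)
    varying = (arr != arr[0]).any(axis=0)
    return np.flatnonzero(good & varying)


def _pair_walk(msa: Msa, pair: tuple[str, str], sites: np.ndarray,
               g_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """(match indicator, score walk) over the polymorphic sites."""
    a = np.frombuffer(msa.row(pair[0]).encode(), dtype="S1")[sites]
    b = np.frombuffer(msa.row(pair[1]).encode(), dtype="S1")[sites]
    match = a == b
    n_match, n_mis = int(match.sum()), int((~match).sum())
    if n_mis == 0:
        penalty = np.inf
    elif g_scale == 0:
        penalty = np.inf
    else:
        penalty = g_scale * n_match / n_mis
    walk = np.where(match, 1.0, -penalty)
    return match, walk


def _max_subarray(walk: np.ndarray) -> float:
    """Best fragment score (max subarray sum, empty fragment -> 0)."""
    finite = np.where(np.isinf(walk), -1e18, walk)
    best = run = 0.0
    for x in finite:
        run = max(0.0, run + x)
        best = max(best, run)
    return best


def _ruzzo_tompa(walk: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal scoring (disjoint) subsequences of the walk.

    Returns (start, end, score) with end exclusive, scores > 0.
    """
    finite = np.where(np.isinf(walk), -1e18, walk)
    # maximal scoring subsequences (Ruzzo & Tompa 1999)
    segs: list[list[float]] = []  # [cum_before_start, cum_at_end, start, end]
    cum = 0.0
    for k, x in enumerate(finite):
        prev_cum = cum
        cum += x
        if x <= 0:
            continue
        seg = [prev_cum, cum, k, k + 1]
        while True:
            j = None
            for idx in range(len(segs) - 1, -1, -1):
                if segs[idx][0] < seg[0]:
                    j = idx
                    break
            if j is None or segs[j][1] >= seg[1]:
                segs.append(seg)
                break
            seg = [segs[j][0], seg[1], segs[j][2], seg[3]]
            segs = segs[:j]
    return [(int(s[2]), int(s[3]), float(s[1] - s[0])) for s in segs
            if s[1] - s[0] > 0]


def sawyer_fragments(msa: Msa, pair: tuple[str, str], sites: np.ndarray,
                     params: SawyerParams | None = None) -> pd.DataFrame:
    """Maximal nonnegative-score fragments for one pair.

    Fragments are found over the polymorphic-site subsequence and reported
    with both site-index and alignment coordinates; those failing the
    minimum span / polymorphism-count / score thresholds are dropped.
    Returned sorted by score descending.
    """
    params = params or SawyerParams()
    if len(sites) == 0:
        return pd.DataFrame(columns=[
            "pair_a", "pair_b", "site_start", "site_end", "aln_start",
            "aln_end", "score", "n_sites", "n_mismatch"])
    match, walk = _pair_walk(msa, pair, sites, params.g_scale)
    rows = []
    for s, e, score in _ruzzo_tompa(walk):
        aln_start = int(sites[s])
        aln_end = int(sites[e - 1]) + 1
        n_sites = e - s
        if aln_end - aln_start < params.min_frag_len:
            continue
        if n_sites < params.min_polymorphisms:
            continue
        if score < params.min_frag_score:
            continue
        rows.append({
            "pair_a": pair[0], "pair_b": pair[1],
            "site_start": s, "site_end": e,
            "aln_start": aln_start, "aln_end": aln_end,
            "score": score, "n_sites": n_sites,
            "n_mismatch": int((~match[s:e]).sum()),
        })
    frags = pd.DataFrame(rows, columns=[
        "pair_a", "pair_b", "site_start", "site_end", "aln_start",
        "aln_end", "score", "n_sites", "n_mismatch"])
    return frags.sort_values("score", ascending=False).reset_index(drop=True)


def _null_best_scores(walk: np.ndarray, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Best fragment score of each column-shuffled replicate (vectorized)."""
    finite = np.where(np.isinf(walk), -1e18, walk)
    mat = np.tile(finite, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    cum = np.cumsum(mat, axis=1)
    cum = np.concatenate([np.zeros((n_perm, 1)), cum], axis=1)
    running_min = np.minimum.accumulate(cum, axis=1)
    best = np.max(cum[:, 1:] - running_min[:, :-1], axis=1)
    return np.maximum(best, 0.0)


def sawyer_pvalue(msa: Msa, group: list[str],
                  params: SawyerParams | None = None,
                  rng: np.random.Generator | int | None = None
                  ) -> pd.DataFrame:
    """Permutation p-values for the best fragment of every pair in a group.

    ``p = (1 + #{null best >= observed}) / (1 + n_permutations)``, then
    Bonferroni-corrected by the number of pairs in the group.  The
    generator must be seeded for reproducibility.
    """
    params = params or SawyerParams()
    if params.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng)
    sites = polymorphic_sites(msa, group)
    pairs = [(a, b) for i, a in enumerate(group) for b in group[i + 1:]]
    n_tests = len(pairs)
    rows = []
    for pair in pairs:
        frags = sawyer_fragments(msa, pair, sites, params)
        if len(sites) == 0:
            obs = 0.0
        else:
            _, walk = _pair_walk(msa, pair, sites, params.g_scale)
            obs = _max_subarray(walk)
        if len(sites) == 0 or np.all(np.isinf(walk)):
            rows.append({
                "pair_a": pair[0], "pair_b": pair[1], "score": obs,
                "p_raw": 1.0, "p_corrected": 1.0,
                "aln_start": np.nan, "aln_end": np.nan,
            })
            continue
        null = _null_best_scores(walk, params.n_permutations, rng)
        if np.allclose(null, null[0]):
            warnings.warn("degenerate permutation null; p set to 1")
            p = 1.0
        else:
            p = (1 + int((null >= obs - 1e-12).sum())) / (
                1 + params.n_permutations
            )
        rows.append({
            "pair_a": pair[0], "pair_b": pair[1], "score": obs,
            "p_raw": p, "p_corrected": min(1.0, p * n_tests),
            "aln_start": frags.aln_start.iloc[0] if len(frags) else np.nan,
            "aln_end": frags.aln_end.iloc[0] if len(frags) else np.nan,
        })
    return pd.DataFrame(rows)


def load_external_regions(path) -> pd.DataFrame:
    """Importer for external-method region tables (RDP, bootscan, ...):
    TSV with columns pair_a, pair_b, start, end, method, p."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pair_a", "pair_b", "start", "end", "method", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external region table missing columns: {missing}")
    return df


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def integrate(candidates: pd.DataFrame,
              colocalized: pd.DataFrame | None = None,
              sawyer: pd.DataFrame | None = None,
              external: pd.DataFrame | None = None,
              alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine evidence lines into conversion calls.

    Returns ``(calls, uncorroborated)``.  Calls carry a tier ("recent" for
    a high-similarity region with >=1 other indicator for the same pair,
    "ancient" for a significant statistic with no high-similarity window),
    the union extent, and the evidence flags.  High-similarity candidates
    with no corroboration are reported separately, not as calls.
    """
    calls, lonely = [], []
    sawyer_sig = (
        sawyer[sawyer.p_corrected < alpha]
        if sawyer is not None and len(sawyer) else pd.DataFrame(
            columns=["pair_a", "pair_b", "score", "p_corrected",
                     "aln_start", "aln_end"])
    )
    for _, cand in candidates.iterrows():
        pair = frozenset([cand.pair_a, cand.pair_b])
        evidence = {"similarity"}
        start, end = int(cand.start), int(cand.end)
        if colocalized is not None and len(colocalized):
            hits = colocalized[
                colocalized.corroborating
                & (colocalized.region_start < end)
                & (colocalized.region_end > start)
            ]
            for _, h in hits.iterrows():
                if pair <= set(h.sharing.split(",")):
                    evidence.add("microindel")
        for _, s in sawyer_sig.iterrows():
            if frozenset([s.pair_a, s.pair_b]) != pair:
                continue
            if np.isnan(s.aln_start) or _overlap(s.aln_start, s.aln_end,
                                                 start, end):
                evidence.add("sawyer")
        if external is not None and len(external):
            for _, x in external.iterrows():
                if frozenset([x.pair_a, x.pair_b]) == pair and _overlap(
                        x.start, x.end, start, end):
                    evidence.add(str(x.method))
        if len(evidence) >= 2:
            calls.append({
                "pair_a": cand.pair_a, "pair_b": cand.pair_b,
                "start": start, "end": end, "tier": "recent",
                "evidence": ",".join(sorted(evidence)),
                "peak_similarity": float(cand.peak),
            })
        else:
            lonely.append({
                "pair_a": cand.pair_a, "pair_b": cand.pair_b,
                "start": start, "end": end,
                "peak_similarity": float(cand.peak),
            })
    # ancient tier: significant statistic without a high-similarity window
    for _, s in sawyer_sig.iterrows():
        pair = frozenset([s.pair_a, s.pair_b])
        if np.isnan(s.aln_start):
            continue
        covered = any(
            frozenset([c.pair_a, c.pair_b]) == pair
            and _overlap(s.aln_start, s.aln_end, c.start, c.end)
            for _, c in candidates.iterrows()
        )
        if not covered:
            calls.append({
                "pair_a": s.pair_a, "pair_b": s.pair_b,
                "start": int(s.aln_start), "end": int(s.aln_end),
                "tier": "ancient", "evidence": "sawyer",
                "peak_similarity": np.nan,
            })
    calls_df = pd.DataFrame(calls, columns=[
        "pair_a", "pair_b", "start", "end", "tier", "evidence",
        "peak_similarity"])
    calls_df = _merge_calls(calls_df)
    lonely_df = pd.DataFrame(lonely, columns=[
        "pair_a", "pair_b", "start", "end", "peak_similarity"])
    return calls_df, lonely_df


def _merge_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping calls for the same pair: union extent, combined
    evidence, best tier (recent beats ancient)."""
    if not len(calls):
        return calls
    out = []
    for (a, b), grp in calls.groupby(["pair_a", "pair_b"], sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, row in grp.iterrows():
            if cur is not None and row.start < cur["end"]:
                cur["end"] = max(cur["end"], int(row.end))
                cur["evidence"] = ",".join(sorted(
                    set(cur["evidence"].split(",")) |
                    set(row.evidence.split(","))))
                if row.tier == "recent":
                    cur["tier"] = "recent"
                if not np.isnan(row.peak_similarity):
                    cur["peak_similarity"] = np.nanmax(
                        [cur["peak_similarity"], row.peak_similarity])
            else:
                if cur is not None:
                    out.append(cur)
                cur = {"pair_a": a, "pair_b": b, "start": int(row.start),
                       "end": int(row.end), "tier": row.tier,
                       "evidence": row.evidence,
                       "peak_similarity": row.peak_similarity}
        out.append(cur)
    return pd.DataFrame(out)
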