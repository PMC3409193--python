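"""Alignment-column classification: parsimony status and codon degeneracy.

Two jobs live here.  First, classify every column of an alignment against a
topology: parsimony-informative (>=2 states each present in >=2 sequences,
gaps and N excluded), minimum possible steps (#distinct states - 1), Fitch
steps on the tree, and from those the *supporting* (informative, no extra
steps) and *homoplasic* (extra steps, i.e. parallel or reverse substitutions
somewhere on the tree) flags.  Second, classify third codon positions by
degeneracy under the standard genetic code; the two-fold degenerate sites
feed the TREx molecular clock.

Degeneracy is assigned *pairwise*: a third position counts as two-fold for a
pair of sequences only when both sequences' codons make it two-fold.  This
avoids artifacts when the codon context differs between the pair.
"""

from __future__ import annotations

import warnings

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from paralogy.msa import Msa, Region
from paralogy.trees import fitch_count, leaf_labels

__all__ = [
    "classify_sites",
    "partition_degeneracy",
    "pairwise_twofold",
    "codon_degeneracy",
]

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def codon_degeneracy(codon: str) -> int | None:
    """Degeneracy (1, 2, 3, or 4) of the third position of ``codon``.

    Returns the number of third-position nucleotides that preserve the
    encoded amino acid; None for stop codons or codons containing gaps/N.
    """
    if len(codon) != 3 or any(c not in _BASES for c in codon):
        return None
    if codon in _STOPS:
        return None
    aa = _CODE[codon]
    return sum(
        1 for b in _BASES
        if codon[:2] + b not in _STOPS and _CODE.get(codon[:2] + b) == aa
    )


def _coding_regions(msa: Msa) -> list[Region]:
    regions = [r for r in msa.regions if r.frame is not None]
    if not regions:
        raise ValueError("no coding region with a declared frame")
    return regions


def _codons_at(msa: Msa, col: int, region: Region):
    """Per-sequence codon containing alignment column ``col``; yields
    (label, codon, position-in-codon) skipping codons with gaps or N."""
    rel = col - (region.start + region.frame)
    if rel < 0:
        return
    pos = rel % 3
    start = col - pos
    if start + 3 > region.end:
        return
    for label, row in zip(msa.labels, msa.rows):
        codon = row[start:start + 3]
        if any(c not in _BASES for c in codon):
            continue
        yield label, codon, pos


def classify_sites(msa: Msa, tree) -> pd.DataFrame:
    """Per-column classification table against one topology.

    Columns: ``column, region, n_states, informative, min_steps,
    steps_on_tree, supporting, homoplasic, synonymous, degeneracy``.
    ``degeneracy`` is set at third codon positions where every ungapped
    sequence agrees on the class (-1 where sequences disagree, NA outside
    coding regions); ``synonymous`` is True where the observed codon
    variants at the column all encode one amino acid.
    """
    tree_leaves = set(leaf_labels(tree))
    if tree_leaves != set(msa.labels):
        diff = sorted(tree_leaves ^ set(msa.labels))
        raise ValueError(f"tree leaves != alignment labels; difference: {diff}")

    region_of = {}
    for r in msa.regions:
        for j in range(r.start, r.end):
            region_of[j] = r

    rows = []
    for j in range(msa.length):
        column = {
            label: (row[j] if row[j] in _BASES else None)
            for label, row in zip(msa.labels, msa.rows)
        }
        counts: dict[str, int] = {}
        for s in column.values():
            if s is not None:
                counts[s] = counts.get(s, 0) + 1
        n_states = len(counts)
        informative = sum(1 for c in counts.values() if c >= 2) >= 2
        min_steps = max(n_states - 1, 0)
        steps = fitch_count(tree, column) if n_states > 1 else 0

        region = region_of.get(j)
        synonymous = False
        degeneracy: float | None = None
        if region is not None and region.frame is not None:
            codons = list(_codons_at(msa, j, region))
            if codons and codons[0][2] == 2:
                degs = {codon_degeneracy(c) for _, c, _ in codons}
                degs.discard(None)
                degeneracy = degs.pop() if len(degs) == 1 else -1
            if n_states > 1 and codons:
                aas = {_CODE[c] for _, c, _ in codons}
                variant = len({c for _, c, _ in codons}) > 1
                synonymous = variant and len(aas) == 1

        rows.append({
            "column": j,
            "region": region.name if region else "",
            "n_states": n_states,
            "informative": informative,
            "min_steps": min_steps,
            "steps_on_tree": steps,
            "supporting": informative and steps == min_steps,
            "homoplasic": steps > min_steps,
            "synonymous": synonymous,
            "degeneracy": degeneracy,
        })
    return pd.DataFrame(rows)


def pairwise_twofold(msa: Msa, pair: tuple[str, str],
                     regions: list[str] | None = None) -> pd.DataFrame:
    """Two-fold degenerate third positions for one sequence pair.

    A column qualifies when both sequences carry complete, stop-free codons
    whose third position is two-fold degenerate *in both* codons.  Returns a
    table with ``column`` and ``changed`` (third-position difference).
    Codons containing an internal stop are excluded with a warning.
    """
    a, b = pair
    row_a, row_b = msa.row(a), msa.row(b)
    coding = _coding_regions(msa)
    if regions is not None:
        coding = [r for r in coding if r.name in regions]
    out = []
    for region in coding:
        start = region.start + region.frame
        for cs in range(start, region.end - 2, 3):
            ca, cb = row_a[cs:cs + 3], row_b[cs:cs + 3]
            if any(c not in _BASES for c in ca + cb):
                continue
            if ca in _STOPS or cb in _STOPS:
                warnings.warn(
                    f"internal stop codon at column {cs}; site excluded"
                )
                continue
            if codon_degeneracy(ca) == 2 and codon_degeneracy(cb) == 2:
                if ca[:2] != cb[:2]:
                    # different codon context: only count when both contexts
                    # admit the same two third-position states
                    set_a = {x for x in _BASES
                             if _CODE.get(ca[:2] + x) == _CODE[ca]}
                    set_b = {x for x in _BASES
                             if _CODE.get(cb[:2] + x) == _CODE[cb]}
                    if set_a != set_b:
                        continue
                out.append({"column": cs + 2, "changed": ca[2] != cb[2]})
    return pd.DataFrame(out, columns=["column", "changed"])


def partition_degeneracy(msa: Msa) -> pd.DataFrame:
    """Pairwise two-fold site tables for every pair of sequences.

    Returns a long table (label_a, label_b, column, changed); the per-pair
    fraction unchanged is the TREx f2 statistic.
    """
    frames = []
    labels = msa.labels
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            t = pairwise_twofold(msa, (a, b))
            t.insert(0, "label_b", b)
            t.insert(0, "label_a", a)
            frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["label_a", "label_b", "column", "changed"]
    )
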