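"""Micro-indel extraction, binary coding, and parsimony over topologies.

A maximal gap run in a row is an indel.  When runs with identical start and
length occur in two or more rows they are coded as one shared binary
character (present=1 / absent=0); a row whose own gap run strictly engulfs
the character's span cannot show presence or absence and is coded missing
('.').  Shared characters are parsimony-informative; singletons are kept
but flagged.  Characters are scored on candidate topologies with Fitch
parsimony (missing leaves pruned per character); an informative character
needing more than one step on a topology is homoplasic with respect to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paralogy.msa import Msa
from paralogy.trees import fitch_count, leaf_labels

__all__ = ["MicroIndelMatrix", "extract_indels", "fitch_steps",
           "compare_topologies", "colocalize", "to_nexus"]

MISSING = -1


@dataclass
class MicroIndelMatrix:
    """Binary-coded shared-gap characters.

    ``characters``: DataFrame with ``start, length, informative, n_present``.
    ``states``: (n_labels, n_characters) int8 array over {0, 1, -1(missing)}.
    """

    labels: list[str]
    characters: pd.DataFrame
    states: np.ndarray

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def informative(self) -> "MicroIndelMatrix":
        mask = self.characters.informative.to_numpy()
        return MicroIndelMatrix(
            list(self.labels),
            self.characters[mask].reset_index(drop=True),
            self.states[:, mask],
        )

    def to_tsv(self, path) -> None:
        sym = {1: "1", 0: "0", MISSING: "."}
        with open(path, "w") as fh:
            header = [f"{r.start}+{r.length}"
                      for r in self.characters.itertuples()]
            fh.write("label\t" + "\t".join(header) + "\n")
            for i, label in enumerate(self.labels):
                fh.write(label + "\t"
                         + "\t".join(sym[int(s)] for s in self.states[i])
                         + "\n")


def _gap_runs(row: str):
    runs, start = [], None
    for i, c in enumerate(row):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(row) - start))
    return runs


def extract_indels(msa: Msa, max_len: int = 100) -> MicroIndelMatrix:
    """Collect per-row maximal gap runs and code identical (start, length)
    runs shared by >=2 rows as binary characters.

    Runs longer than ``max_len`` never become characters (but still create
    missing states where they engulf another character's span).  Singleton
    runs are retained, flagged uninformative.
    """
    runs_by_row = [_gap_runs(row) for row in msa.rows]
    tally: dict[tuple[int, int], list[int]] = {}
    for i, runs in enumerate(runs_by_row):
        for run in runs:
            if run[1] <= max_len:
                tally.setdefault(run, []).append(i)

    chars = sorted(tally)
    states = np.zeros((msa.n, len(chars)), dtype=np.int8)
    rows = []
    for k, (start, length) in enumerate(chars):
        carriers = tally[(start, length)]
        states[carriers, k] = 1
        for i, runs in enumerate(runs_by_row):
            if i in carriers:
                continue
            for rs, rl in runs:
                if rs <= start and rs + rl >= start + length and (rs, rl) != (start, length):
                    states[i, k] = MISSING
                    break
        n_present = len(carriers)
        n_absent = int((states[:, k] == 0).sum())
        rows.append({
            "start": start, "length": length,
            "n_present": n_present,
            "informative": n_present >= 2 and n_absent >= 2,
        })
    characters = pd.DataFrame(
        rows, columns=["start", "length", "n_present", "informative"]
    )
    return MicroIndelMatrix(list(msa.labels), characters, states)


@dataclass
class ParsimonyReport:
    topology_id: str
    total_steps: int
    per_character: pd.DataFrame  # start, length, informative, steps, homoplasic


def fitch_steps(mim: MicroIndelMatrix, tree, topology_id: str = "tree"
                ) -> ParsimonyReport:
    """Fitch parsimony of every character on one topology.

    Tree leaves must cover the matrix labels (extra leaves are simply
    unobserved).  Missing states place no constraint.  A character with <2
    non-missing distinct states costs 0 steps and is flagged degenerate.
    """
    leaves = set(leaf_labels(tree))
    missing = [l for l in mim.labels if l not in leaves]
    if missing:
        raise ValueError(f"labels absent from tree: {missing}")
    rows = []
    for k in range(mim.n_characters):
        col = mim.states[:, k]
        states = {
            label: (None if s == MISSING else int(s))
            for label, s in zip(mim.labels, col)
        }
        observed = {s for s in states.values() if s is not None}
        degenerate = len(observed) < 2
        steps = 0 if degenerate else fitch_count(tree, states)
        info = bool(mim.characters.informative.iloc[k])
        rows.append({
            "start": int(mim.characters.start.iloc[k]),
            "length": int(mim.characters.length.iloc[k]),
            "informative": info,
            "degenerate": degenerate,
            "steps": steps,
            "homoplasic": info and steps > 1,
        })
    per_character = pd.DataFrame(rows, columns=[
        "start", "length", "informative", "degenerate", "steps",
        "homoplasic"])
    return ParsimonyReport(topology_id, int(per_character.steps.sum()),
                           per_character)


def compare_topologies(mim: MicroIndelMatrix, trees: dict[str, object]
                       ) -> list[ParsimonyReport]:
    """Score the matrix on each candidate topology; reports sorted by total
    steps ascending, each annotated with the delta to the best."""
    if len(trees) < 2:
        raise ValueError("need at least 2 topologies to compare")
    reports = [fitch_steps(mim, tree, tid) for tid, tree in trees.items()]
    reports.sort(key=lambda r: r.total_steps)
    best = reports[0].total_steps
    for r in reports:
        r.delta_to_best = r.total_steps - best
    return reports


def colocalize(report: ParsimonyReport, mim: MicroIndelMatrix,
               regions: pd.DataFrame) -> pd.DataFrame:
    """Annotate homoplasic characters with overlapping candidate regions.

    ``regions`` is a candidate-region table (pair_a, pair_b, start, end).
    Each homoplasic character is matched to every overlapping region; the
    character's sharing labels (state 1) are compared with the region's
    pair, and ``corroborating`` is set when the region's pair both carry the
    indel.  Characters without an overlapping region are retained as
    orphans.
    """
    out = []
    homo = report.per_character[report.per_character.homoplasic]
    for idx, ch in homo.iterrows():
        k = int(idx)
        sharing = [
            mim.labels[i] for i in np.flatnonzero(mim.states[:, k] == 1)
        ]
        c_start, c_end = int(ch.start), int(ch.start) + int(ch.length)
        overlaps = regions[
            (regions.start < c_end) & (regions.end > c_start)
        ] if len(regions) else regions
        if overlaps is None or len(overlaps) == 0:
            out.append({
                "char_start": c_start, "char_length": int(ch.length),
                "sharing": ",".join(sharing),
                "region_start": np.nan, "region_end": np.nan,
                "region_pair": "", "corroborating": False,
                "orphan": True,
            })
            continue
        for _, reg in overlaps.iterrows():
            pair = {reg.pair_a, reg.pair_b}
            out.append({
                "char_start": c_start, "char_length": int(ch.length),
                "sharing": ",".join(sharing),
                "region_start": int(reg.start), "region_end": int(reg.end),
                "region_pair": f"{reg.pair_a},{reg.pair_b}",
                "corroborating": pair <= set(sharing),
                "orphan": False,
            })
    return pd.DataFrame(out, columns=[
        "char_start", "char_length", "sharing", "region_start",
        "region_end", "region_pair", "corroborating", "orphan",
    ])


def to_nexus(mim: MicroIndelMatrix, path) -> None:
    """Export the binary matrix as NEXUS standard data (for cross-checking
    in external parsimony programs)."""
    sym = {1: "1", 0: "0", MISSING: "?"}
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(mim.labels)} "
                 f"NCHAR={mim.n_characters};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("  MATRIX\n")
        for i, label in enumerate(mim.labels):
            seq = "".join(sym[int(s)] for s in mim.states[i])
            fh.write(f"    {label} {seq}\n")
        fh.write("  ;\nEND;\n")
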