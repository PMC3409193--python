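"""Gene-family simulator with known natural history.

Generates alignments whose every feature is on record: a species tree (an
ultrametric newick with branch lengths in years, all tips at the present),
gene duplications and losses placed at stated times (including on a stem
above the species-tree root, where pre-speciation duplications live),
TN93 nucleotide substitution, a Poisson micro-indel process, and gene
conversion events that overwrite a recipient tract with the donor's
sequence at the event time.

The simulator emits the *true* alignment: insertions create columns (gap
in every other lineage), deletions leave gap columns, and no realignment
ever happens, so inference modules are tested in isolation from aligner
noise.  All lineages advance in lockstep between events, which is what
lets a conversion copy the donor's state at the moment of the event.

Everything is reproducible from (config, seed); the emitted ground truth
records duplications, losses, realized conversion tracts and indels in
final alignment coordinates, and true pairwise divergence times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paralogy.distances import tn93_transition_probs
from paralogy.msa import Msa, Region
from paralogy.trees import tree_from_newick

__all__ = ["Duplication", "Loss", "Conversion", "SimConfig", "SimTruth",
           "simulate_family", "simulate_silent_pair",
           "make_paper_like_family", "PRESETS"]

GAP = 4
_CHARS = np.array([b"A", b"C", b"G", b"T", b"-"])


@dataclass(frozen=True)
class Duplication:
    time: float                    # years before present
    paralog: str                   # parent paralog to copy
    new_name: str
    chimera_with: str | None = None   # 3' parent of a chimeric duplicate
    breakpoint: float = 0.5        # fraction of columns taken from 5' parent


@dataclass(frozen=True)
class Loss:
    time: float
    species: str                   # species-tree branch (leaf label or
    paralog: str                   # comma-joined descendant leaf labels)
    pseudogenize: bool = False     # keep the sequence, flag it


@dataclass(frozen=True)
class Conversion:
    time: float
    species: str
    donor: str                     # paralog names within that lineage
    recipient: str
    start: float | None = None     # fractional position; None = uniform
    mean_tract: float = 500.0      # geometric tract-length mean
    length: int | None = None      # exact length override


@dataclass
class SimConfig:
    species_newick: str
    length: int = 5000
    regions: list[tuple[str, int, int | None]] = field(default_factory=list)
    root_stem: float = 0.0         # years of stem above the species root
    subs_rate: float = 1.5e-9      # substitutions / site / year
    kappa1: float = 4.0
    kappa2: float = 4.0
    freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    indel_rate: float = 0.0        # events / site / year / lineage
    indel_mean_len: float = 4.0
    duplications: list[Duplication] = field(default_factory=list)
    losses: list[Loss] = field(default_factory=list)
    conversions: list[Conversion] = field(default_factory=list)
    founding_paralog: str = "P1"
    seed: int | None = None        # mandatory at simulate time

    def __post_init__(self):
        if not self.regions:
            self.regions = [("R1", self.length, None)]
        if sum(r[1] for r in self.regions) != self.length:
            raise ValueError("region lengths must sum to sequence length")
        if self.subs_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class SimTruth:
    leaves: dict[str, int]                 # label -> lineage id
    parents: dict[int, tuple[int | None, float]]  # id -> (parent, birth time)
    descendants: dict[int, list[str]]      # lineage id -> descendant leaves
    duplications: pd.DataFrame
    losses: pd.DataFrame
    conversions: pd.DataFrame              # realized tracts, final coords
    indels: pd.DataFrame                   # final coords
    column_origin: np.ndarray              # -1 root, else insertion record id
    pseudogenes: list[str] = field(default_factory=list)

    def divergence_time(self, label_a: str, label_b: str) -> float:
        """True time (years) since the two leaves' lineages split."""
        if label_a == label_b:
            return 0.0
        chain_a = []
        x = self.leaves[label_a]
        while x is not None:
            chain_a.append(x)
            x = self.parents[x][0]
        pos = {lid: k for k, lid in enumerate(chain_a)}
        x, below_b = self.leaves[label_b], None
        while x not in pos:
            below_b = x
            x = self.parents[x][0]
        below_a = chain_a[pos[x] - 1] if pos[x] > 0 else None
        times = [self.parents[c][1] for c in (below_a, below_b)
                 if c is not None]
        return max(times)


class _Lineage:
    __slots__ = ("id", "species_node", "paralog", "seq", "alive")

    def __init__(self, lid, species_node, paralog, seq):
        self.id = lid
        self.species_node = species_node
        self.paralog = paralog
        self.seq = seq
        self.alive = True


def _node_ages(tree):
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child_ages = []
            for c in node.child_nodes():
                child_ages.append(ages[c] + (c.edge.length or 0.0))
            if max(child_ages) - min(child_ages) > 1e-3 * max(
                    max(child_ages), 1.0):
                raise ValueError("species tree must be ultrametric")
            ages[node] = float(np.mean(child_ages))
    return ages


def _branch_token(node) -> str:
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return ",".join(leaves)


def simulate_family(config: SimConfig, seed: int | None = None
                    ) -> tuple[Msa, SimTruth]:
    """Run the simulation; returns the true alignment and its ground truth.

    ``seed`` overrides ``config.seed``; one of them is mandatory.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory")
    rng = np.random.default_rng(seed)

    tree = tree_from_newick(config.species_newick)
    ages = _node_ages(tree)
    root = tree.seed_node
    t0 = ages[root] + config.root_stem
    freqs = np.asarray(config.freqs, dtype=float)

    # events, processed from the past toward the present
    events: list[tuple[float, int, str, object]] = []
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            events.append((ages[node], 0, _branch_token(node), node))
    for d in config.duplications:
        events.append((d.time, 1, d.new_name, d))
    for l in config.losses:
        events.append((l.time, 2, l.paralog, l))
    for c in config.conversions:
        events.append((c.time, 3, c.recipient, c))
    events.sort(key=lambda e: (-e[0], e[1], e[2]))
    for t, _, _, _ in events:
        if t > t0 or t < 0:
            raise ValueError(f"event time {t} outside [0, {t0}]")

    # alignment bookkeeping
    col_ids = list(range(config.length))
    next_col_id = config.length
    region_names = []
    for name, length, _ in config.regions:
        region_names.extend([name] * length)
    col_region = list(region_names)

    root_seq = rng.choice(4, size=config.length, p=freqs).astype(np.int8)
    lineages = [_Lineage(0, root, config.founding_paralog, root_seq)]
    next_id = 1
    parents: dict[int, tuple[int | None, float]] = {0: (None, t0)}

    dup_log, loss_log, conv_log, indel_log = [], [], [], []
    insertion_owner: dict[int, int] = {}   # col_id -> indel record index
    pseudogenes: set[int] = set()

    def live():
        return [ln for ln in lineages if ln.alive]

    def advance(dt):
        nonlocal next_col_id
        if dt <= 0:
            return
        if config.subs_rate > 0:
            d = config.subs_rate * dt
            P = tn93_transition_probs(d, config.kappa1, config.kappa2, freqs)
            cum = P.cumsum(axis=1)
            for ln in live():
                sites = np.flatnonzero(ln.seq != GAP)
                if len(sites) == 0:
                    continue
                u = rng.random(len(sites))
                ln.seq[sites] = (
                    u[:, None] > cum[ln.seq[sites]]
                ).sum(axis=1).astype(np.int8)
        if config.indel_rate > 0:
            for ln in live():
                n_sites = int((ln.seq != GAP).sum())
                n_events = rng.poisson(config.indel_rate * n_sites * dt)
                for _ in range(n_events):
                    length = int(rng.geometric(1 / config.indel_mean_len))
                    if rng.random() < 0.5:          # deletion
                        sites = np.flatnonzero(ln.seq != GAP)
                        if len(sites) == 0:
                            continue
                        k = rng.integers(len(sites))
                        span = sites[k:k + length]
                        ln.seq[span] = GAP
                        indel_log.append({
                            "lineage": ln.id, "kind": "del",
                            "col_ids": [col_ids[j] for j in span],
                            "length": len(span),
                        })
                    else:                           # insertion
                        pos = int(rng.integers(len(ln.seq) + 1))
                        new_ids = list(range(next_col_id,
                                             next_col_id + length))
                        next_col_id += length
                        bases = rng.choice(4, size=length, p=freqs
                                           ).astype(np.int8)
                        rec = len(indel_log)
                        indel_log.append({
                            "lineage": ln.id, "kind": "ins",
                            "col_ids": new_ids, "length": length,
                        })
                        for cid in new_ids:
                            insertion_owner[cid] = rec
                        region = (col_region[pos - 1] if pos > 0
                                  else col_region[0])
                        col_ids[pos:pos] = new_ids
                        col_region[pos:pos] = [region] * length
                        for other in live():
                            fill = bases if other is ln else np.full(
                                length, GAP, dtype=np.int8)
                            other.seq = np.concatenate(
                                [other.seq[:pos], fill, other.seq[pos:]])

    def find_lineage(paralog, species_token=None):
        cands = [ln for ln in live() if ln.paralog == paralog]
        if species_token is not None:
            cands = [ln for ln in cands
                     if _branch_token(ln.species_node) == species_token
                     or ln.species_node.taxon is not None
                     and ln.species_node.taxon.label == species_token]
        if not cands:
            raise ValueError(f"no live lineage for paralog {paralog!r}")
        if len(cands) > 1:
            raise ValueError(
                f"ambiguous lineage for paralog {paralog!r}; give species")
        return cands[0]

    now = t0
    for time, kind, _, payload in events:
        advance(now - time)
        now = time
        if kind == 0:                                   # speciation
            node = payload
            for ln in [l for l in live() if l.species_node is node]:
                ln.alive = False
                for child in node.child_nodes():
                    nonloc = _Lineage(next_id, child, ln.paralog,
                                      ln.seq.copy())
                    parents[next_id] = (ln.id, time)
                    if ln.id in pseudogenes:
                        pseudogenes.add(next_id)
                    lineages.append(nonloc)
                    next_id += 1
        elif kind == 1:                                 # duplication
            d = payload
            parent = find_lineage(d.paralog)
            if d.chimera_with is not None:
                parent2 = find_lineage(d.chimera_with)
                bp = int(round(d.breakpoint * len(parent.seq)))
                seq = np.concatenate([parent.seq[:bp], parent2.seq[bp:]])
            else:
                seq = parent.seq.copy()
            lineages.append(_Lineage(next_id, parent.species_node,
                                     d.new_name, seq))
            parents[next_id] = (parent.id, time)
            dup_log.append({
                "time": time, "paralog": d.new_name, "parent": d.paralog,
                "chimera_with": d.chimera_with, "lineage": next_id,
            })
            next_id += 1
        elif kind == 2:                                 # loss
            l = payload
            ln = find_lineage(l.paralog, l.species)
            if l.pseudogenize:
                pseudogenes.add(ln.id)
            else:
                ln.alive = False
            loss_log.append({
                "time": time, "species": l.species, "paralog": l.paralog,
                "pseudogenized": l.pseudogenize,
            })
        else:                                           # conversion
            c = payload
            donor = find_lineage(c.donor, c.species)
            recipient = find_lineage(c.recipient, c.species)
            if c.length is not None:
                length = int(c.length)
            else:
                length = int(rng.geometric(1 / c.mean_tract))
            L = len(recipient.seq)
            length = min(length, L)
            if c.start is not None:
                start = int(round(c.start * L))
            else:
                start = int(rng.integers(0, L - length + 1))
            start = min(start, L - length)
            recipient.seq[start:start + length] = \
                donor.seq[start:start + length]
            conv_log.append({
                "time": time, "species": c.species,
                "donor": c.donor, "recipient": c.recipient,
                "recipient_lineage": recipient.id,
                "col_id_first": col_ids[start],
                "col_id_last": col_ids[start + length - 1],
                "tract_length": length,
            })
    advance(now)

    # emit leaves
    final_pos = {cid: k for k, cid in enumerate(col_ids)}
    labels, rows, species_of, leaves = [], [], {}, {}
    for ln in live():
        if not ln.species_node.is_leaf():
            raise RuntimeError("live lineage not at a species tip")
        sp = ln.species_node.taxon.label
        label = f"{sp}_{ln.paralog}"
        labels.append(label)
        rows.append(b"".join(_CHARS[ln.seq]).decode())
        species_of[label] = sp
        leaves[label] = ln.id

    regions, start = [], 0
    for name, _, frame in config.regions:
        n_cols = sum(1 for r in col_region if r == name)
        regions.append(Region(name, start, start + n_cols, frame))
        start += n_cols
    # col_region stays grouped because insertions inherit a neighbour region
    msa = Msa(labels, rows, regions, species_of)

    children: dict[int, list[int]] = {}
    for cid, (pid, _) in parents.items():
        if pid is not None:
            children.setdefault(pid, []).append(cid)
    descendants: dict[int, list[str]] = {}

    def desc(lid):
        if lid in descendants:
            return descendants[lid]
        out = [lbl for lbl, l_id in leaves.items() if l_id == lid]
        for ch in children.get(lid, []):
            out.extend(desc(ch))
        descendants[lid] = out
        return out

    for lid in parents:
        desc(lid)

    conv_df = pd.DataFrame(conv_log, columns=[
        "time", "species", "donor", "recipient", "recipient_lineage",
        "col_id_first", "col_id_last", "tract_length"])
    if len(conv_df):
        conv_df["start"] = [final_pos[c] for c in conv_df.col_id_first]
        conv_df["end"] = [final_pos[c] + 1 for c in conv_df.col_id_last]
    else:
        conv_df["start"] = conv_df["end"] = []

    indel_rows = []
    for rec in indel_log:
        pos = sorted(final_pos[c] for c in rec["col_ids"])
        indel_rows.append({
            "lineage": rec["lineage"], "kind": rec["kind"],
            "start": pos[0] if pos else -1,
            "end": (pos[-1] + 1) if pos else -1,
            "length": rec["length"],
            "contiguous": bool(pos) and pos[-1] - pos[0] + 1 == len(pos),
        })
    indel_df = pd.DataFrame(indel_rows, columns=[
        "lineage", "kind", "start", "end", "length", "contiguous"])

    origin = np.full(len(col_ids), -1, dtype=int)
    for cid, rec in insertion_owner.items():
        origin[final_pos[cid]] = rec

    truth = SimTruth(
        leaves=leaves,
        parents=parents,
        descendants=descendants,
        duplications=pd.DataFrame(dup_log, columns=[
            "time", "paralog", "parent", "chimera_with", "lineage"]),
        losses=pd.DataFrame(loss_log, columns=[
            "time", "species", "paralog", "pseudogenized"]),
        conversions=conv_df,
        indels=indel_df,
        column_origin=origin,
        pseudogenes=[lbl for lbl, lid in leaves.items()
                     if lid in pseudogenes],
    )
    return msa, truth


def simulate_silent_pair(T: float, n: int, rate: float = 3.1e-9,
                         p1: float = 0.52,
                         rng: np.random.Generator | int | None = None
                         ) -> float:
    """Observed fraction-unchanged of ``n`` two-fold sites for a pair that
    diverged ``T`` years ago, under the stationary two-state silent model.

    Each lineage substitutes at ``rate`` per site per year; states start at
    the (p1, 1-p1) equilibrium.  Returns the realized f2.
    """
    rng = np.random.default_rng(rng)
    p2 = 1 - p1
    lam = rate / (2 * p1 * p2)          # eigenvalue of the two-state chain
    e = math.exp(-lam * T)
    anc = rng.random(n) < p1            # True = state 1
    out = []
    for _ in range(2):
        stay1 = p1 + p2 * e
        stay2 = p2 + p1 * e
        u = rng.random(n)
        tip = np.where(anc, u < stay1, ~(u < stay2))
        out.append(tip)
    return float((out[0] == out[1]).mean())


# ---------------------------------------------------------------------------
# presets mirroring the study regime

def _fourparalog_oneloss() -> SimConfig:
    return SimConfig(
        species_newick="((Homo:28000000,Mac:28000000):12000000,"
                       "Cal:40000000);",
        root_stem=25e6,
        length=12500,
        regions=[("intron1", 1700, None), ("intron2", 1500, None),
                 ("intron3", 1600, None), ("intron4", 1500, None),
                 ("intron5", 1600, None), ("intron6", 1500, None),
                 ("intron7", 1600, None), ("intron8", 1500, None)],
        subs_rate=1.3e-9,
        indel_rate=2e-11,
        indel_mean_len=4.0,
        duplications=[
            Duplication(62e6, "P1", "P2"),
            Duplication(61e6, "P2", "P3"),
            Duplication(60e6, "P3", "P4"),
        ],
        losses=[
            Loss(20e6, "Homo", "P1"),
            Loss(15e6, "Mac", "P1", pseudogenize=True),
        ],
        conversions=[
            Conversion(8e6, "Mac", donor="P2", recipient="P3",
                       start=0.30, length=900),
        ],
    )


def _chimeric_dup() -> SimConfig:
    return SimConfig(
        species_newick="(A:30000000);",
        root_stem=30e6,
        length=4800,
        regions=[(f"intron{i}", 800, None) for i in range(1, 7)],
        subs_rate=2.0e-9,
        duplications=[
            Duplication(55e6, "P1", "P2"),
            Duplication(50e6, "P2", "P3"),
            Duplication(20e6, "P1", "PX", chimera_with="P3",
                        breakpoint=0.5),
        ],
    )


def _conversion_group(with_conversion: bool) -> SimConfig:
    conversions = []
    if with_conversion:
        conversions = [Conversion(2.5e6, "X", donor="P1", recipient="P3",
                                  length=800)]
    return SimConfig(
        species_newick="(X:10000000);",
        root_stem=30e6,
        length=5000,
        subs_rate=2.0e-9,
        duplications=[
            Duplication(38e6, "P1", "P2"),
            Duplication(36e6, "P2", "P3"),
            Duplication(34e6, "P3", "P4"),
        ],
        conversions=conversions,
    )


PRESETS = {
    "fourparalog_oneloss": _fourparalog_oneloss,
    "chimeric_dup": _chimeric_dup,
    "no_conversion": lambda: _conversion_group(False),
    "one_conversion": lambda: _conversion_group(True),
}


def make_paper_like_family(preset: str, seed: int) -> tuple[Msa, SimTruth]:
    """Simulate one of the registered study-regime presets."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    return simulate_family(PRESETS[preset](), seed=seed)
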