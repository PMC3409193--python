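"""Pairwise evolutionary distances, ortholog assignment, and NJ trees.

The default distance is a composite-likelihood TN93 estimator: the base
frequencies and the two transition/transversion rate ratios are estimated
once from the whole alignment (shared across pairs, the defining feature of
"maximum composite likelihood" distances), after which each pair's distance
is the per-pair maximum-likelihood branch length under TN93 with those
shared parameters.  Simpler estimators (p-distance, Jukes-Cantor, Kimura
2-parameter) are selectable and serve as cross-checks.

Gap handling follows pairwise deletion: a column contributes to a pair iff
neither member carries a gap or N there.  Variances are delta-method /
observed-information estimates on the per-pair site counts.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

import skbio
from skbio.tree import nj as _skbio_nj

from paralogy.msa import Msa
from paralogy.trees import tree_from_newick

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "group_averages",
    "within_species_pairs",
    "OrthologMap",
    "assign_orthologs",
    "neighbor_joining",
    "per_region_nearest",
    "tn93_transition_probs",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with variances and compared-site counts.

    Entries may be NaN where a distance is undefined (no comparable sites or
    saturation)."""

    labels: list[str]
    d: np.ndarray
    var: np.ndarray | None = None
    n_sites: np.ndarray | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.d), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        finite = ~np.isnan(self.d)
        if not np.allclose(
            np.where(finite & finite.T, self.d - self.d.T, 0.0), 0, atol=1e-12
        ):
            raise ValueError("matrix not symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.d[finite] < -1e-12):
                raise ValueError("negative distances")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @property
    def is_complete(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return not np.isnan(self.d[off]).any()

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                if np.isnan(self.d[i, j]):
                    out.append((a, self.labels[j]))
        return out

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            list(labels),
            self.d[np.ix_(idx, idx)],
            None if self.var is None else self.var[np.ix_(idx, idx)],
            None if self.n_sites is None else self.n_sites[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# TN93 model machinery (shared with the simulator)

def tn93_transition_probs(d: float, kappa1: float, kappa2: float,
                          freqs: np.ndarray) -> np.ndarray:
    """TN93 transition probability matrix after ``d`` expected subs/site.

    Base order A, C, G, T.  ``kappa1`` is the purine-transition /
    transversion rate ratio, ``kappa2`` the pyrimidine one.
    """
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    # total substitution rate with transversion rate beta = 1
    mu = 2 * gA * gG * kappa1 + 2 * gC * gT * kappa2 + 2 * gR * gY
    t = d / mu
    e2 = np.exp(-t)
    e3 = np.exp(-(gR * kappa1 + gY) * t)
    e4 = np.exp(-(gY * kappa2 + gR) * t)

    P = np.empty((4, 4))
    for i, gi in enumerate(freqs):
        for j, gj in enumerate(freqs):
            pur_i, pur_j = i in (0, 2), j in (0, 2)
            if pur_i and pur_j:
                if i == j:
                    P[i, j] = gj + gj * (gY / gR) * e2 + ((gR - gj) / gR) * e3
                else:
                    P[i, j] = gj + gj * (gY / gR) * e2 - (gj / gR) * e3
            elif not pur_i and not pur_j:
                if i == j:
                    P[i, j] = gj + gj * (gR / gY) * e2 + ((gY - gj) / gY) * e4
                else:
                    P[i, j] = gj + gj * (gR / gY) * e2 - (gj / gY) * e4
            else:
                P[i, j] = gj * (1 - e2)
    return P


def _pair_counts(arr: np.ndarray, i: int, j: int) -> np.ndarray:
    """4x4 ordered base-pair counts over columns where neither row is gapped."""
    a, b = arr[i], arr[j]
    counts = np.zeros((4, 4))
    codes_a = np.full(a.shape, -1, dtype=np.int8)
    codes_b = np.full(b.shape, -1, dtype=np.int8)
    for base, k in _BASE_INDEX.items():
        codes_a[a == base.encode()] = k
        codes_b[b == base.encode()] = k
    ok = (codes_a >= 0) & (codes_b >= 0)
    np.add.at(counts, (codes_a[ok], codes_b[ok]), 1)
    return counts


def _tn93_loglik(d, counts, kappa1, kappa2, freqs):
    P = tn93_transition_probs(d, kappa1, kappa2, freqs)
    probs = freqs[:, None] * P
    with np.errstate(divide="ignore"):
        ll = counts * np.log(np.maximum(probs, 1e-300))
    return float(ll.sum())


def _tn93_mle(counts, kappa1, kappa2, freqs, d_max=10.0):
    res = minimize_scalar(
        lambda d: -_tn93_loglik(d, counts, kappa1, kappa2, freqs),
        bounds=(1e-9, d_max), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def _estimate_shared_kappas(count_list, freqs):
    """Maximize the composite likelihood over (kappa1, kappa2), profiling
    out each pair's distance."""

    def neg(params):
        k1, k2 = np.exp(params)
        total = 0.0
        for counts in count_list:
            _, ll = _tn93_mle(counts, k1, k2, freqs)
            total += ll
        return -total

    res = minimize(neg, x0=np.log([4.0, 4.0]), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    return tuple(np.exp(res.x))


# ---------------------------------------------------------------------------

def _closed_form(model: str, counts: np.ndarray):
    """(d, var) for p/JC/K2P from a 4x4 pair count matrix; NaN on saturation."""
    n = counts.sum()
    if n == 0:
        return np.nan, np.nan
    mismatch = n - np.trace(counts)
    p = mismatch / n
    if model == "p":
        return p, p * (1 - p) / n
    if model == "jc":
        arg = 1 - 4 * p / 3
        if arg <= 0:
            return np.nan, np.nan
        d = -0.75 * np.log(arg)
        return d, p * (1 - p) / (n * arg ** 2)
    if model == "k2p":
        ti = (counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1])
        P = ti / n
        Q = p - P
        a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
        if a1 <= 0 or a2 <= 0:
            return np.nan, np.nan
        d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        c1, c2 = 1 / a1, 0.5 * (1 / a1 + 1 / a2)
        var = (c1 ** 2 * P + c2 ** 2 * Q - (c1 * P + c2 * Q) ** 2) / n
        return d, var
    raise ValueError(f"unknown model {model!r}")


def pairwise_distance(msa: Msa, model: str = "tn93") -> DistanceMatrix:
    """Pairwise distance matrix under ``model`` in {p, jc, k2p, tn93}.

    Pairwise gap deletion: a column is used for a pair iff neither member
    has a gap or N there.  Pairs with no comparable sites, or saturated
    under the chosen correction, get NaN with a warning.
    """
    if msa.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = msa.array()
    k = msa.n
    d = np.zeros((k, k))
    var = np.zeros((k, k))
    n_sites = np.zeros((k, k))

    pair_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    count_list = [_pair_counts(arr, i, j) for i, j in pair_idx]

    if model == "tn93":
        flat = np.zeros(4)
        for base, idx in _BASE_INDEX.items():
            flat[idx] = (arr == base.encode()).sum()
        freqs = flat / flat.sum()
        kappa1, kappa2 = _estimate_shared_kappas(
            [c for c in count_list if c.sum() > 0], freqs
        )

    for (i, j), counts in zip(pair_idx, count_list):
        n = counts.sum()
        n_sites[i, j] = n_sites[j, i] = n
        if n == 0:
            warnings.warn(
                f"pair ({msa.labels[i]}, {msa.labels[j]}) has no comparable "
                "sites; distance undefined"
            )
            dij, vij = np.nan, np.nan
        elif model == "tn93":
            dij, ll = _tn93_mle(counts, kappa1, kappa2, freqs)
            if dij > 9.0:
                warnings.warn(
                    f"pair ({msa.labels[i]}, {msa.labels[j]}) appears "
                    "saturated; distance undefined"
                )
                dij, vij = np.nan, np.nan
            else:
                h = 1e-5 * max(dij, 1e-3)
                second = (
                    _tn93_loglik(dij + h, counts, kappa1, kappa2, freqs)
                    - 2 * ll
                    + _tn93_loglik(max(dij - h, 1e-12), counts, kappa1,
                                   kappa2, freqs)
                ) / h ** 2
                vij = -1.0 / second if second < 0 else np.nan
        else:
            dij, vij = _closed_form(model, counts)
            if np.isnan(dij):
                warnings.warn(
                    f"pair ({msa.labels[i]}, {msa.labels[j]}) saturated "
                    f"under {model}; distance undefined"
                )
        d[i, j] = d[j, i] = dij
        var[i, j] = var[j, i] = vij
    return DistanceMatrix(list(msa.labels), d, var, n_sites)


# ---------------------------------------------------------------------------

def within_species_pairs(dm: DistanceMatrix, species_of: dict[str, str],
                         species: str | None = None,
                         exclude: set[str] | None = None):
    """All same-species label pairs (optionally one species; optionally
    excluding labels, e.g. a removed chimera)."""
    exclude = exclude or set()
    out = []
    for i, a in enumerate(dm.labels):
        for b in dm.labels[i + 1:]:
            if a in exclude or b in exclude:
                continue
            if species_of[a] != species_of[b]:
                continue
            if species is not None and species_of[a] != species:
                continue
            out.append((a, b))
    return out


def group_averages(dm: DistanceMatrix,
                   contrasts: dict[str, list[tuple[str, str]]]) -> pd.DataFrame:
    """Unweighted mean and sample sd of the listed pairwise entries.

    NaN entries are excluded and counted in ``n_na``; an empty contrast
    yields NaN mean with a reason.
    """
    rows = []
    for name, pairs in contrasts.items():
        vals = np.array([dm.get(a, b) for a, b in pairs], dtype=float)
        ok = vals[~np.isnan(vals)]
        rows.append({
            "contrast": name,
            "n": len(ok),
            "n_na": int(np.isnan(vals).sum()),
            "mean": float(ok.mean()) if len(ok) else np.nan,
            "sd": float(ok.std(ddof=1)) if len(ok) > 1 else np.nan,
            "note": "" if len(ok) else "empty contrast",
        })
    return pd.DataFrame(rows)


@dataclass
class OrthologMap:
    """Best interspecies partner per (label, foreign species).

    ``table`` has one row per candidate assignment; ``pairs`` lists the
    mutually-best, unambiguous ortholog pairs."""

    table: pd.DataFrame
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def partner(self, label: str, species: str) -> str:
        t = self.table
        row = t[(t.label == label) & (t.partner_species == species)]
        if row.empty:
            raise KeyError((label, species))
        return row.iloc[0]["partner"]


def assign_orthologs(dm: DistanceMatrix, species_of: dict[str, str],
                     tol: float = 1e-9) -> OrthologMap:
    """Smallest-pairwise-distance ortholog assignment.

    For each label and each foreign species, the minimum-distance partner
    is reported with the margin to the second-best candidate.  Ties within
    ``tol`` are flagged ambiguous; two labels claiming the same partner are
    flagged as conflicts rather than silently resolved.
    """
    species = sorted(set(species_of[l] for l in dm.labels))
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    rows = []
    for label in dm.labels:
        for sp in species:
            if sp == species_of[label]:
                continue
            cands = [
                (dm.get(label, other), other)
                for other in dm.labels
                if species_of[other] == sp and not np.isnan(dm.get(label, other))
            ]
            if not cands:
                continue
            cands.sort()
            best_d, best = cands[0]
            second = cands[1][0] if len(cands) > 1 else np.nan
            ambiguous = len(cands) > 1 and (second - best_d) <= tol
            rows.append({
                "label": label, "species": species_of[label],
                "partner": best, "partner_species": sp,
                "distance": best_d,
                "margin": second - best_d if len(cands) > 1 else np.nan,
                "ambiguous": ambiguous,
            })
    table = pd.DataFrame(rows)
    # conflicts: a partner claimed as best by >1 label of the same species
    conflict = np.zeros(len(table), dtype=bool)
    for (_, _), grp in table.groupby(["partner", "species"]):
        if len(grp) > 1:
            conflict[grp.index] = True
    table["conflict"] = conflict
    pairs = []
    for _, row in table.iterrows():
        if row.ambiguous or row.conflict:
            continue
        back = table[
            (table.label == row.partner)
            & (table.partner_species == row.species)
        ]
        if not back.empty and back.iloc[0]["partner"] == row.label:
            key = tuple(sorted([row.label, row.partner]))
            if not any((p[0], p[1]) == key for p in pairs):
                pairs.append((key[0], key[1], float(row.distance)))
    return OrthologMap(table, pairs)


def neighbor_joining(dm: DistanceMatrix):
    """Neighbor-joining tree (unrooted, with branch lengths) from a complete
    distance matrix; returns a dendropy Tree."""
    if not dm.is_complete:
        raise ValueError(f"NA entries for pairs: {dm.missing_pairs()}")
    sk = skbio.DistanceMatrix(dm.d, ids=dm.labels)
    tree = _skbio_nj(sk)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return tree_from_newick(buf.getvalue())


def per_region_nearest(msa: Msa, model: str = "p", min_sites: int = 100):
    """Nearest same-species paralog per region, with chimera diagnostics.

    Returns ``(table, flags)``.  ``table`` has one row per (region, label)
    with the minimum-distance same-species paralog; regions shorter than
    ``min_sites`` are flagged low-confidence.  ``flags`` carries one row per
    label with a chimera signal: set when the 5' block and 3' block of
    confident regions have different nearest parents, each consistent over
    >=2 contiguous regions.
    """
    if len(msa.regions) < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for region in msa.regions:
        sub = msa.slice(region.start, region.end)
        dm = pairwise_distance(sub, model=model)
        low = region.length < min_sites
        for label in msa.labels:
            sib = [
                (dm.get(label, other), other)
                for other in msa.labels
                if other != label
                and msa.species_of[other] == msa.species_of[label]
                and not np.isnan(dm.get(label, other))
            ]
            if not sib:
                continue
            dist, nearest = min(sib)
            rows.append({
                "region": region.name, "label": label,
                "nearest": nearest, "distance": dist,
                "low_confidence": low,
            })
    table = pd.DataFrame(rows)

    region_order = [r.name for r in msa.regions]
    flag_rows = []
    for label in msa.labels:
        t = table[(table.label == label) & (~table.low_confidence)]
        parents = [
            t[t.region == rname].iloc[0]["nearest"]
            for rname in region_order
            if not t[t.region == rname].empty
        ]
        chimera, breakpoint_index = False, None
        for k in range(2, len(parents) - 1):
            head, tail = parents[:k], parents[k:]
            if (len(set(head)) == 1 and len(set(tail)) == 1
                    and head[0] != tail[0] and len(tail) >= 2):
                chimera, breakpoint_index = True, k
                break
        flag_rows.append({
            "label": label,
            "chimera": chimera,
            "parent_5p": parents[0] if chimera else None,
            "parent_3p": parents[-1] if chimera else None,
            "breakpoint_after_region": (
                None if breakpoint_index is None
                else region_order[breakpoint_index - 1]
            ),
        })
    return table, pd.DataFrame(flag_rows)
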