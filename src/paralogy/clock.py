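"""Molecular-clock placement of gene duplications.

Two clocks are implemented.  The TREx clock dates a pair of coding
sequences from the fraction *f2* of two-fold degenerate third positions
that remain unchanged: under a two-state substitution process with
equilibrium silent-site bias (p1, p2), identity decays as

    f2(T) = q + (1 - q) * exp(-2 r T / (1 - q)),      q = p1^2 + p2^2,

where r is the silent substitution rate per site per year and T the time
since the pair's common ancestor (the factor 2 counts both diverging
lineages; a per-lineage convention is available behind a flag).  The decay
constant 2r/(1-q) is fixed so that the *initial* loss of identity per year
equals 2r, which is what the quoted rate constant measures.  Inverting
gives the date; f2 at or below the equilibrium identity q means the pair
is saturated and undatable.

The second clock is relative: paralog intron distances are compared with
ortholog intron distances across known speciation splits, using a filtered
panel of reference introns (no long conserved noncoding sequence, not
within 15 Mbp of a telomere, normal GC) as neutral yardsticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from paralogy.msa import Msa
from paralogy.sites import pairwise_twofold

__all__ = ["ClockParams", "TrexDate", "f2_statistic", "trex_date",
           "filter_reference_introns", "place_duplications"]


@dataclass
class ClockParams:
    rate: float = 3.1e-9            # silent substitutions / site / year
    p1: float = 0.52                # equilibrium silent-site bias (AT)
    p2: float = 0.48                # (GC)
    two_lineage: bool = True        # T measures total time since divergence

    def __post_init__(self):
        if abs(self.p1 + self.p2 - 1) > 1e-9:
            raise ValueError("p1 + p2 must equal 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def q(self) -> float:
        """Equilibrium identity at a two-fold site (p1^2 + p2^2)."""
        return self.p1 ** 2 + self.p2 ** 2

    @property
    def decay(self) -> float:
        """Exponential decay constant per year."""
        factor = 2.0 if self.two_lineage else 1.0
        return factor * self.rate / (1 - self.q)


def f2_statistic(msa: Msa, pair: tuple[str, str],
                 regions: list[str] | None = None) -> tuple[float, int]:
    """Fraction of pairwise two-fold degenerate sites unchanged, and their
    count.  (nan, 0) when the pair has no comparable two-fold sites."""
    table = pairwise_twofold(msa, pair, regions=regions)
    n = len(table)
    if n == 0:
        return math.nan, 0
    return float((~table.changed).mean()), n


@dataclass
class TrexDate:
    date: float            # years since divergence
    lo: float
    hi: float
    saturated: bool = False


def trex_date(f2: float, n: int, params: ClockParams | None = None,
              z: float = 1.96) -> TrexDate:
    """Invert the f2 decay curve for the divergence date.

    The confidence interval propagates the binomial error on f2 through the
    inversion.  f2 <= q (at or below the equilibrium plateau) is reported
    as saturated with an infinite date rather than extrapolated.
    """
    params = params or ClockParams()
    q = params.q

    def invert(f):
        if f >= 1.0:
            return 0.0
        if f <= q:
            return math.inf
        return -math.log((f - q) / (1 - q)) / params.decay

    if f2 <= q:
        return TrexDate(math.inf, math.inf, math.inf, saturated=True)
    date = invert(f2)
    if n > 0:
        se = math.sqrt(max(f2 * (1 - f2), 0.0) / n)
        lo = invert(min(f2 + z * se, 1.0))
        hi = invert(max(f2 - z * se, 0.0))
    else:
        lo = hi = math.nan
    return TrexDate(date, lo, hi, saturated=False)


def filter_reference_introns(refs: pd.DataFrame,
                             gc_max: float = 45.0,
                             telomere_min_mbp: float = 15.0,
                             drop_lcns: bool = True,
                             drop_mrna: bool = False
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen reference introns for clock suitability.

    Expects columns ``gene, gc_percent, telomere_mbp, lcns, in_mrna``.
    A record is kept iff GC <= gc_max, telomere distance >= telomere_min_mbp,
    and (when ``drop_lcns``) it holds no long conserved noncoding sequence.
    Presence in an mRNA database is *not* disqualifying by default (it does
    not imply functional constraint).  Records with missing metadata are
    excluded with reason "incomplete".  Returns (kept, exclusion_log).
    """
    kept, log = [], []
    needed = ["gene", "gc_percent", "telomere_mbp", "lcns", "in_mrna"]
    for _, row in refs.iterrows():
        if any(pd.isna(row.get(c)) for c in needed):
            log.append({"gene": row.get("gene"), "reasons": "incomplete"})
            continue
        reasons = []
        if row.gc_percent > gc_max:
            reasons.append(f"GC {row.gc_percent}% > {gc_max}%")
        if row.telomere_mbp < telomere_min_mbp:
            reasons.append(
                f"{row.telomere_mbp} Mbp from telomere < {telomere_min_mbp}")
        if drop_lcns and bool(row.lcns):
            reasons.append("LCNS")
        if drop_mrna and bool(row.in_mrna):
            reasons.append("in mRNA database")
        if reasons:
            log.append({"gene": row.gene, "reasons": "; ".join(reasons)})
        else:
            kept.append(row)
    kept_df = pd.DataFrame(kept).reset_index(drop=True) if kept else \
        refs.iloc[0:0].copy()
    return kept_df, pd.DataFrame(log, columns=["gene", "reasons"])


def place_duplications(paralog_mean: float, paralog_sd: float,
                       splits: pd.DataFrame) -> pd.DataFrame:
    """Place duplications relative to speciation splits by distance.

    ``splits`` has columns ``split, mean, sd`` giving the ortholog intron
    distance distribution across each speciation split.  Verdict per split:
    "before" when the paralog mean exceeds the split's ortholog mean by
    more than one pooled sd (duplication older than the speciation),
    "after" when it falls short by more than one pooled sd, else
    "unresolved".  Missing split statistics yield "unresolved" with a
    reason.
    """
    rows = []
    for _, s in splits.iterrows():
        if pd.isna(s.get("mean")):
            rows.append({"split": s.split, "ortholog_mean": np.nan,
                         "delta": np.nan, "pooled_sd": np.nan,
                         "verdict": "unresolved",
                         "reason": "missing split reference"})
            continue
        sd_o = 0.0 if pd.isna(s.get("sd")) else float(s.sd)
        sd_p = 0.0 if pd.isna(paralog_sd) else float(paralog_sd)
        pooled = math.sqrt(sd_p ** 2 + sd_o ** 2)
        delta = paralog_mean - float(s["mean"])
        if pooled == 0:
            verdict = ("before" if delta > 0 else
                       "after" if delta < 0 else "unresolved")
        elif delta > pooled:
            verdict = "before"
        elif delta < -pooled:
            verdict = "after"
        else:
            verdict = "unresolved"
        rows.append({"split": s.split, "ortholog_mean": float(s["mean"]),
                     "delta": delta, "pooled_sd": pooled,
                     "verdict": verdict, "reason": ""})
    return pd.DataFrame(rows)
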