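"""Sliding-window pairwise similarity ("similarity calculator").

Within each window, identities score 1.0 and mismatches 0; columns where
either member of the pair carries a gap or N are skipped, and when skipped
columns exceed the gap tolerance (default 20% of the window) no score is
reported for that window.  Windows advance by a configurable step (default
1 nt) and are indexed by their start column; a final partial window is not
scored.  Runs of consecutive windows above the similarity threshold
(default 0.96, chosen against an orthologous-background similarity of about
0.94) become candidate converted regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paralogy.msa import Msa

__all__ = ["ScanParams", "windowed_similarity", "candidate_regions",
           "plot_tracks"]


@dataclass
class ScanParams:
    window: int = 250          # 150 is the conventional exonic window
    step: int = 1
    max_gap_fraction: float = 0.20
    threshold: float = 0.96

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0 < self.step <= self.window):
            raise ValueError("step must be in (0, window]")
        if not (0 <= self.max_gap_fraction < 1):
            raise ValueError("max_gap_fraction must be in [0, 1)")


def windowed_similarity(msa: Msa, pair: tuple[str, str],
                        params: ScanParams | None = None) -> pd.DataFrame:
    """Similarity track for one pair: columns ``start, center, score``.

    ``score`` is NaN for windows whose gapped-site fraction exceeds
    ``max_gap_fraction``.
    """
    params = params or ScanParams()
    if params.window > msa.length:
        raise ValueError("window larger than alignment")
    a = np.frombuffer(msa.row(pair[0]).encode(), dtype="S1")
    b = np.frombuffer(msa.row(pair[1]).encode(), dtype="S1")
    good = np.isin(a, [b"A", b"C", b"G", b"T"]) & np.isin(
        b, [b"A", b"C", b"G", b"T"]
    )
    ident = (a == b) & good

    cum_good = np.concatenate([[0], np.cumsum(good)])
    cum_ident = np.concatenate([[0], np.cumsum(ident)])
    starts = np.arange(0, msa.length - params.window + 1, params.step)
    n_good = cum_good[starts + params.window] - cum_good[starts]
    n_ident = cum_ident[starts + params.window] - cum_ident[starts]
    gap_frac = 1 - n_good / params.window
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(
            gap_frac > params.max_gap_fraction, np.nan,
            np.where(n_good > 0, n_ident / np.maximum(n_good, 1), np.nan),
        )
    return pd.DataFrame({
        "pair_a": pair[0], "pair_b": pair[1],
        "start": starts, "center": starts + params.window // 2,
        "score": score,
    })


def candidate_regions(tracks: list[pd.DataFrame],
                      params: ScanParams | None = None) -> pd.DataFrame:
    """Maximal runs of consecutive scored windows above the threshold.

    One row per run and pair: ``pair_a, pair_b, start, end, peak`` with
    ``[start, end)`` in alignment coordinates (end = last window start +
    window length).  Unscored (NaN) windows break runs.
    """
    params = params or ScanParams()
    out = []
    for track in tracks:
        hot = (track.score > params.threshold).to_numpy()
        if not hot.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8),
                                                       [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            seg = track.iloc[lo:hi]
            out.append({
                "pair_a": track.iloc[0]["pair_a"],
                "pair_b": track.iloc[0]["pair_b"],
                "start": int(seg.iloc[0]["start"]),
                "end": int(seg.iloc[-1]["start"]) + params.window,
                "peak": float(seg.score.max()),
                "n_windows": int(hi - lo),
            })
    return pd.DataFrame(
        out, columns=["pair_a", "pair_b", "start", "end", "peak", "n_windows"]
    )


def plot_tracks(tracks: list[pd.DataFrame], ax=None, threshold=None):
    """Simple per-pair similarity figure (one line per pair)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for track in tracks:
        label = f"{track.iloc[0]['pair_a']}:{track.iloc[0]['pair_b']}"
        ax.plot(track.center, track.score, lw=0.8, label=label)
    if threshold is not None:
        ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("alignment position")
    ax.set_ylabel("similarity")
    ax.legend(fontsize=7, ncol=2)
    return ax
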