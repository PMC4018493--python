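"""Per-site signal quantification and constitutive/inducible classification.

Each consensus site gets a library-normalized read count per condition in
a summit-centered window, an inducibility ratio I = stimulated/resting,
and inhibitor sensitivity ratios (LatB/stimulated, U0126/stimulated).  A
pseudocount keeps all ratios finite at empty sites.

The inducibility threshold is not fixed a priori: it is selected so that
a through-origin regression of stimulated on resting counts over the
sub-threshold ("constitutive") population has slope closest to 1 — a
population unaffected by signal should lie on the diagonal.  Sites above
the selected threshold are called inducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, SignalTrack, window_count

RATIO_COLUMNS = ("inducibility", "latB_ratio", "u0126_ratio")


@dataclass
class ThresholdFit:
    """Result of the slope-closest-to-1 threshold search."""

    threshold: float
    slope_constitutive: float
    grid: np.ndarray  # shape (n, 2): evaluated (t, slope) pairs


def quantify_sites(
    sites: Sequence,
    tracks: Mapping[str, SignalTrack],
    window_bp: int = 400,
    pseudocount: float = 1.0,
    normalize_to: float = 1e6,
) -> pd.DataFrame:
    """Summit-centered normalized counts per condition plus ratio columns.

    ``sites`` need ``id``, ``chrom`` and ``summit_pos``; ``tracks`` maps
    condition names (resting/stimulated/LatB/U0126) to SignalTracks.
    Returns a DataFrame indexed by site id.  The pseudocount is added
    before every ratio, never to the stored counts.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be positive and even")
    half = window_bp // 2
    rows = {}
    for site in sites:
        counts = {}
        for cond, track in tracks.items():
            iv = GenomicInterval(site.chrom,
                                 max(site.summit_pos - half, 0),
                                 site.summit_pos + half)
            counts[cond] = window_count(track, iv, normalize_to=normalize_to)
        rows[site.id] = counts
        if hasattr(site, "signal"):
            site.signal.update(counts)
    df = pd.DataFrame.from_dict(rows, orient="index")
    pc = pseudocount
    if {"resting", "stimulated"} <= set(df.columns):
        df["inducibility"] = (df["stimulated"] + pc) / (df["resting"] + pc)
    if {"LatB", "stimulated"} <= set(df.columns):
        df["latB_ratio"] = (df["LatB"] + pc) / (df["stimulated"] + pc)
    if {"U0126", "stimulated"} <= set(df.columns):
        df["u0126_ratio"] = (df["U0126"] + pc) / (df["stimulated"] + pc)
    return df


def make_ratio_fns(
    tracks: Mapping[str, SignalTrack],
    window_bp: int = 400,
    pseudocount: float = 1.0,
    normalize_to: float = 1e6,
):
    """(inducibility_fn, latB_fn) closures over condition tracks.

    Used by the consensus rescue rules, which need ratios for candidate
    locations that are not yet part of any quantified site table.
    """
    half = window_bp // 2

    def _count(cond: str, site) -> float:
        iv = GenomicInterval(site.chrom, max(site.summit_pos - half, 0),
                             site.summit_pos + half)
        return window_count(tracks[cond], iv, normalize_to=normalize_to)

    def inducibility_fn(site) -> float:
        return (_count("stimulated", site) + pseudocount) / (
            _count("resting", site) + pseudocount)

    def latB_fn(site) -> float:
        return (_count("LatB", site) + pseudocount) / (
            _count("stimulated", site) + pseudocount)

    return inducibility_fn, latB_fn


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.nan
    return float(np.dot(x, y) / denom)


def select_threshold(
    signals: pd.DataFrame,
    grid: np.ndarray | None = None,
    min_sites: int = 50,
    min_below: int = 10,
) -> ThresholdFit:
    """Pick the inducibility threshold whose constitutive slope is closest to 1.

    For each candidate t the through-origin least-squares slope of
    stimulated on resting counts is computed over sites with I < t; the t
    minimizing |slope - 1| wins, smallest t on ties.  The regression is in
    raw normalized count space and is invariant to rescaling both
    conditions by a common factor.
    """
    if grid is None:
        grid = np.arange(1.05, 3.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if len(signals) < min_sites:
        raise ValueError(
            f"need at least {min_sites} sites to fit a threshold, "
            f"got {len(signals)}"
        )
    x = signals["resting"].to_numpy(dtype=float)
    y = signals["stimulated"].to_numpy(dtype=float)
    ratios = signals["inducibility"].to_numpy(dtype=float)
    if int((ratios < grid[0]).sum()) < min_below:
        raise ValueError(
            f"fewer than {min_below} sites below the smallest grid value "
            f"{grid[0]:g}: degenerate partition"
        )
    slopes = np.empty_like(grid)
    for i, t in enumerate(grid):
        mask = ratios < t
        slopes[i] = _through_origin_slope(x[mask], y[mask])
    best = int(np.nanargmin(np.abs(slopes - 1.0)))
    return ThresholdFit(
        threshold=float(grid[best]),
        slope_constitutive=float(slopes[best]),
        grid=np.column_stack([grid, slopes]),
    )


def classify_sites(
    signals: pd.DataFrame, threshold: float
) -> tuple[pd.Series, pd.DataFrame]:
    """Partition sites into constitutive / inducible at the given threshold.

    Inducible means I strictly greater than the threshold (a site exactly
    at the threshold is constitutive).  Also returns per-class n and
    mean +/- SEM of the inducibility ratio.
    """
    labels = pd.Series(
        np.where(signals["inducibility"] > threshold, "inducible",
                 "constitutive"),
        index=signals.index, name="class",
    )
    rows = []
    for cls in ("constitutive", "inducible"):
        vals = signals.loc[labels == cls, "inducibility"]
        n = len(vals)
        rows.append({
            "class": cls, "n": n,
            "mean_inducibility": float(vals.mean()) if n else np.nan,
            "sem_inducibility": float(vals.std(ddof=1) / np.sqrt(n))
            if n > 1 else np.nan,
        })
    return labels, pd.DataFrame(rows).set_index("class")


def sensitivity_flags(
    signals: pd.DataFrame,
    latB_cut: float = 0.67,
    u0126_cut: float = 0.67,
) -> pd.DataFrame:
    """Inhibitor sensitivity: signal loss of at least 1 - cut vs stimulated."""
    out = pd.DataFrame(index=signals.index)
    if "latB_ratio" in signals:
        out["latB_sensitive"] = signals["latB_ratio"] < latB_cut
    if "u0126_ratio" in signals:
        out["u0126_sensitive"] = signals["u0126_ratio"] < u0126_cut
    return out
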