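"""Cofactor assignment at SRF sites: MRTF, TCF, both, or solo.

Each consensus SRF site is classified by overlap with the MRTF and TCF
consensus site sets; sites bound by both families are refined by a
binding-score dominance rule (a more than twofold score difference marks
one family as dominant).  MRTF sites with no detectable SRF are retained
as an orphan list rather than discarded.

The binding score is the library-normalized read count in a
summit-centered window under the family's maximally active condition
(stimulated for MRTF, resting for TCF).  This definition is this
package's own operationalization — configurable through the ``track``
argument — since a score can be any monotone readout of occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import GenomicInterval, SignalTrack, window_count
from .peak_consensus import Site

COFACTOR_CLASSES = ("MRTF", "TCF", "both", "solo")


@dataclass
class CofactorCall:
    site: Site
    cofactor_class: str
    mrtf_score: float = np.nan
    tcf_score: float = np.nan

    @property
    def refined_class(self) -> str:
        return dominance(self.mrtf_score, self.tcf_score,
                         base=self.cofactor_class)


def _build_trees(sites: Sequence[Site], slop: int = 0) -> dict:
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(
            s.interval.start - slop, s.interval.end + slop, s)
    return trees


def assign_cofactors(
    srf_sites: Sequence[Site],
    mrtf_sites: Sequence[Site],
    tcf_sites: Sequence[Site],
    slop: int = 0,
) -> tuple[list[CofactorCall], list[Site]]:
    """Overlap-based cofactor class per SRF site, plus orphan MRTF sites.

    Returns ``(calls, orphan_mrtf)``: the calls partition the SRF sites
    exhaustively and exclusively into MRTF / TCF / both / solo; orphans
    are MRTF sites that touch no SRF site.
    """
    mrtf_trees = _build_trees(mrtf_sites, slop)
    tcf_trees = _build_trees(tcf_sites, slop)
    srf_trees = _build_trees(srf_sites, slop)
    calls = []
    for s in srf_sites:
        has_mrtf = bool(mrtf_trees.get(s.chrom, IntervalTree())
                        .overlap(s.interval.start, s.interval.end))
        has_tcf = bool(tcf_trees.get(s.chrom, IntervalTree())
                       .overlap(s.interval.start, s.interval.end))
        cls = ("both" if has_mrtf and has_tcf
               else "MRTF" if has_mrtf
               else "TCF" if has_tcf
               else "solo")
        calls.append(CofactorCall(s, cls))
    orphans = [
        m for m in mrtf_sites
        if not srf_trees.get(m.chrom, IntervalTree())
        .overlap(m.interval.start, m.interval.end)
    ]
    return calls, orphans


def binding_score(
    site,
    track: SignalTrack,
    window_bp: int = 400,
    normalize_to: float = 1e6,
) -> float:
    """Normalized read count in the summit-centered window (>= 0, monotone)."""
    half = window_bp // 2
    iv = GenomicInterval(site.chrom, max(site.summit_pos - half, 0),
                         site.summit_pos + half)
    return window_count(track, iv, normalize_to=normalize_to)


def dominance(mrtf_score: float, tcf_score: float, fold: float = 2.0,
              base: str = "both") -> str:
    """Refine a dual-bound site by a >fold score difference.

    Antisymmetric under swapping the scores; non-"both" classes pass
    through unchanged.
    """
    if base != "both":
        return base
    if mrtf_score > fold * tcf_score:
        return "both-dominant-MRTF"
    if tcf_score > fold * mrtf_score:
        return "both-dominant-TCF"
    return "both"


def score_calls(
    calls: Sequence[CofactorCall],
    mrtf_track: SignalTrack,
    tcf_track: SignalTrack,
    window_bp: int = 400,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Fill in binding scores and dominance; returns a tidy table."""
    rows = []
    for c in calls:
        c.mrtf_score = binding_score(c.site, mrtf_track, window_bp)
        c.tcf_score = binding_score(c.site, tcf_track, window_bp)
        rows.append({
            "site_id": c.site.id,
            "chrom": c.site.chrom,
            "summit": c.site.summit_pos,
            "cofactor_class": c.cofactor_class,
            "mrtf_score": c.mrtf_score,
            "tcf_score": c.tcf_score,
            "refined_class": dominance(c.mrtf_score, c.tcf_score, fold,
                                       c.cofactor_class),
        })
    return pd.DataFrame(rows).set_index("site_id")


def mrtf_ab_concordance(
    mrtf_sites: Sequence[Site],
    trackA: SignalTrack,
    trackB: SignalTrack,
    window_bp: int = 400,
) -> pd.DataFrame:
    """Spearman correlation of MRTF-A vs MRTF-B read counts per call label.

    Strata follow the site evidence labels {A+B, A-only, B-only}.  A high
    correlation in the B-only stratum indicates that B-only calls reflect
    antibody sensitivity, not MRTF-B-specific binding.
    """
    rows = []
    per_label: dict[str, list[tuple[float, float]]] = {}
    for s in mrtf_sites:
        a = binding_score(s, trackA, window_bp)
        b = binding_score(s, trackB, window_bp)
        per_label.setdefault(s.label or "?", []).append((a, b))
        per_label.setdefault("all", []).append((a, b))
    for label, pairs in sorted(per_label.items()):
        arr = np.asarray(pairs)
        if len(arr) >= 3 and np.ptp(arr[:, 0]) > 0 and np.ptp(arr[:, 1]) > 0:
            rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
        else:
            rho, p = np.nan, np.nan
        rows.append({"label": label, "n": len(arr),
                     "spearman_rho": rho, "p": p})
    return pd.DataFrame(rows).set_index("label")
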