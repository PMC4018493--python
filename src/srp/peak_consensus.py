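"""Consensus binding-site definition from per-sample peak calls.

Per-sample peaks (MACS-style calls supplied as narrowPeak) are combined
into consensus SRF, MRTF and TCF site sets using replication rules plus a
permissive "rescue" pass:

* SRF core: union of peaks detected in both resting samples, in both
  stimulated samples, in the LatB sample and any other sample, or in the
  U0126 sample and any other sample (all at the stringent threshold).
* SRF rescue: additional sites passing only a low threshold (P < 0.05)
  that coincide with a stringent MRTF peak and show serum-inducible,
  LatB-sensitive SRF signal.
* MRTF: peaks detected in more than one sample per antibody or by both
  MRTF-A and MRTF-B in the same condition (the two heterodimerize);
  rescue at the low threshold for peaks coincident with an inducible,
  LatB-sensitive SRF site.
* TCF (SAP-1, Elk-1, Net): signal in more than one condition for the same
  family member, or for multiple members in the same condition.

Coincidence defaults to >=1 bp interval overlap (slop 0); overlapping
contributing peaks are merged transitively into a single site whose
summit is that of the lowest-p contributing peak (leftmost on ties).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .core_io import GenomicInterval, Peak

SRF_SAMPLE_LABELS = ("resting1", "resting2", "stim1", "stim2", "LatB", "U0126")

_site_counter = itertools.count()


@dataclass
class Site:
    """A consensus binding site with its supporting evidence."""

    interval: GenomicInterval
    summit: int  # absolute genomic coordinate
    antibody_family: str  # {"SRF", "MRTF", "TCF"}
    evidence: list[tuple[str, float]] = field(default_factory=list)
    rescued: bool = False
    rescue_rule: str | None = None
    label: str | None = None  # e.g. MRTF evidence class {A-only, B-only, A+B}
    signal: dict[str, float] = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a Site needs at least one evidence entry")
        if not self.id:
            self.id = f"{self.antibody_family}_{next(_site_counter):05d}"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit_pos(self) -> int:
        return self.summit

    def overlaps_peak(self, peak: Peak, slop: int = 0) -> bool:
        return self.interval.overlaps(peak.interval, slop=slop)


def cluster_peaks(peaks: Sequence[Peak], slop: int = 0) -> list[list[Peak]]:
    """Transitively merge overlapping peaks (single sorted sweep).

    Chained overlaps (A-B, B-C, no A-C) end up in one cluster: a single
    genomic locus is represented once.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.interval.start,
                                           p.interval.end))
    clusters: list[list[Peak]] = []
    cur: list[Peak] = []
    cur_chrom, cur_end = None, -1
    for p in ordered:
        if cur and p.chrom == cur_chrom and p.interval.start - slop < cur_end + slop:
            cur.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [p]
            cur_chrom, cur_end = p.chrom, p.interval.end
    if cur:
        clusters.append(cur)
    return clusters


def _site_from_cluster(cluster: Sequence[Peak], family: str,
                       rescued: bool = False,
                       rescue_rule: str | None = None) -> Site:
    start = min(p.interval.start for p in cluster)
    end = max(p.interval.end for p in cluster)
    best = min(cluster, key=lambda p: (p.pvalue, p.summit_pos))
    return Site(
        interval=GenomicInterval(cluster[0].chrom, start, end),
        summit=best.summit_pos,
        antibody_family=family,
        evidence=[(p.sample or "?", p.pvalue) for p in cluster],
        rescued=rescued,
        rescue_rule=rescue_rule,
    )


def _stringent(peaks: Iterable[Peak], stringent_p: float) -> list[Peak]:
    return [p for p in peaks if p.pvalue < stringent_p]


def _renumber(sites: list[Site], prefix: str) -> list[Site]:
    """Deterministic ids in genomic order (independent of process state)."""
    sites.sort(key=lambda s: (s.chrom, s.interval.start, s.interval.end))
    for i, s in enumerate(sites):
        s.id = f"{prefix}_{i:05d}"
    return sites


# ---------------------------------------------------------------------------
# SRF
# ---------------------------------------------------------------------------

def call_srf_core(
    srf_peaks_by_sample: dict[str, Sequence[Peak]],
    stringent_p: float = 1e-5,
    slop: int = 0,
) -> list[Site]:
    """Core SRF consensus from the four replication/coincidence clauses.

    Samples must be labeled resting1, resting2, stim1, stim2, LatB, U0126.
    """
    missing = [s for s in SRF_SAMPLE_LABELS if s not in srf_peaks_by_sample]
    if missing:
        raise KeyError(f"missing required SRF sample label(s): {missing}")
    pool: list[Peak] = []
    for label in SRF_SAMPLE_LABELS:
        for p in _stringent(srf_peaks_by_sample[label], stringent_p):
            p.sample = label
            pool.append(p)
    sites = []
    for cluster in cluster_peaks(pool, slop=slop):
        samples = {p.sample for p in cluster}
        ok = (
            {"resting1", "resting2"} <= samples
            or {"stim1", "stim2"} <= samples
            or ("LatB" in samples and len(samples) > 1)
            or ("U0126" in samples and len(samples) > 1)
        )
        if ok:
            sites.append(_site_from_cluster(cluster, "SRF"))
    return _renumber(sites, "SRF")


def rescue_srf(
    candidate_srf_low_p: Sequence[Peak],
    core_sites: Sequence[Site],
    mrtf_stringent_peaks: Sequence[Peak],
    inducibility_fn: Callable[[Site], float],
    latB_fn: Callable[[Site], float],
    low_p: float = 0.05,
    inducibility_threshold: float = 1.5,
    latB_cut: float = 0.67,
    slop: int = 0,
) -> list[Site]:
    """SRF sites admitted below the stringent threshold.

    A candidate cluster is rescued when it does not touch the core set,
    passes the low threshold, coincides with a stringent MRTF peak, and its
    read ratios show serum induction above ``inducibility_threshold`` with
    LatB sensitivity below ``latB_cut``.  Rescued sites are flagged and are
    disjoint from the core set by construction.
    """
    candidates = [p for p in candidate_srf_low_p if p.pvalue < low_p]
    rescued = []
    for cluster in cluster_peaks(candidates, slop=slop):
        site = _site_from_cluster(cluster, "SRF", rescued=True,
                                  rescue_rule="mrtf_inducible_latB")
        if any(site.interval.overlaps(c.interval, slop=slop)
               for c in core_sites):
            continue
        if not any(site.overlaps_peak(m, slop=slop)
                   for m in mrtf_stringent_peaks):
            continue
        if inducibility_fn(site) <= inducibility_threshold:
            continue
        if latB_fn(site) >= latB_cut:
            continue
        rescued.append(site)
    return _renumber(rescued, "SRFr")


# ---------------------------------------------------------------------------
# MRTF
# ---------------------------------------------------------------------------

def _mrtf_label(cluster: Sequence[Peak]) -> str:
    antibodies = {p.antibody for p in cluster}
    if antibodies >= {"MRTF-A", "MRTF-B"}:
        return "A+B"
    return "A-only" if "MRTF-A" in antibodies else "B-only"


def call_mrtf(
    mrtfA_peaks: Sequence[Peak],
    mrtfB_peaks: Sequence[Peak],
    srf_inducible_latB_sensitive_sites: Sequence[Site],
    stringent_p: float = 1e-5,
    low_p: float = 0.05,
    slop: int = 0,
) -> list[Site]:
    """MRTF consensus: the two-antibody replication rules plus SRF rescue.

    Peaks must carry ``antibody`` ("MRTF-A"/"MRTF-B"), ``sample`` and
    ``condition``.  Primary sites satisfy, at the stringent threshold,
    (1) detection in more than one sample for one antibody, or (2)
    detection by both antibodies in the same condition.  Remaining peaks at
    the low threshold coincident with an inducible, LatB-sensitive SRF
    site are rescued.  Site labels record the antibody evidence class.
    """
    pool = _stringent(list(mrtfA_peaks) + list(mrtfB_peaks), stringent_p)
    primary: list[Site] = []
    for cluster in cluster_peaks(pool, slop=slop):
        per_ab_samples: dict[str, set] = {}
        per_cond_abs: dict[str, set] = {}
        for p in cluster:
            per_ab_samples.setdefault(p.antibody, set()).add(p.sample)
            per_cond_abs.setdefault(p.condition, set()).add(p.antibody)
        rule1 = any(len(s) > 1 for s in per_ab_samples.values())
        rule2 = any(abs >= {"MRTF-A", "MRTF-B"}
                    for abs in per_cond_abs.values())
        if rule1 or rule2:
            site = _site_from_cluster(cluster, "MRTF")
            site.label = _mrtf_label(cluster)
            primary.append(site)

    low_pool = [
        p for p in list(mrtfA_peaks) + list(mrtfB_peaks)
        if p.pvalue < low_p
    ]
    rescued: list[Site] = []
    for cluster in cluster_peaks(low_pool, slop=slop):
        site = _site_from_cluster(cluster, "MRTF", rescued=True,
                                  rescue_rule="srf_inducible_latB")
        if any(site.interval.overlaps(s.interval, slop=slop) for s in primary):
            continue
        if not any(site.interval.overlaps(s.interval, slop=slop)
                   for s in srf_inducible_latB_sensitive_sites):
            continue
        site.label = _mrtf_label(cluster)
        rescued.append(site)
    return _renumber(primary + rescued, "MRTF")


# ---------------------------------------------------------------------------
# TCF
# ---------------------------------------------------------------------------

TCF_MEMBERS = ("SAP-1", "Elk-1", "Net")


def call_tcf(
    tcf_peaks: Sequence[Peak],
    stringent_p: float = 1e-5,
    slop: int = 0,
) -> list[Site]:
    """TCF consensus from SAP-1 / Elk-1 / Net peak calls.

    A locus qualifies with signal in more than one condition for the same
    family member, or for multiple members in the same condition (all at
    the stringent threshold).
    """
    pool = [p for p in tcf_peaks if p.pvalue < stringent_p]
    for p in pool:
        if p.antibody not in TCF_MEMBERS:
            raise ValueError(f"unexpected TCF antibody {p.antibody!r}")
    sites = []
    for cluster in cluster_peaks(pool, slop=slop):
        per_member_conds: dict[str, set] = {}
        per_cond_members: dict[str, set] = {}
        for p in cluster:
            per_member_conds.setdefault(p.antibody, set()).add(p.condition)
            per_cond_members.setdefault(p.condition, set()).add(p.antibody)
        rule1 = any(len(c) > 1 for c in per_member_conds.values())
        rule2 = any(len(m) > 1 for m in per_cond_members.values())
        if rule1 or rule2:
            site = _site_from_cluster(cluster, "TCF")
            site.label = "+".join(sorted(per_member_conds))
            sites.append(site)
    return _renumber(sites, "TCF")
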