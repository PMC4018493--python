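"""Consensus rules vs quoted-rule examples and a brute-force oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from srp.peak_consensus import (
    Site,
    call_mrtf,
    call_srf_core,
    call_tcf,
    cluster_peaks,
    rescue_srf,
)
from tests.conftest import make_peak

SRF_LABELS = ("resting1", "resting2", "stim1", "stim2", "LatB", "U0126")


# --------------------------------------------------------------------- oracle

def brute_clusters(peaks):
    """Connected components of the pairwise-overlap graph (independent of
    the sweep implementation)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i, j in itertools.combinations(range(len(peaks)), 2):
        a, b = peaks[i], peaks[j]
        if a.chrom == b.chrom and a.interval.start < b.interval.end \
                and b.interval.start < a.interval.end:
            g.add_edge(i, j)
    return [[peaks[i] for i in comp]
            for comp in nx.connected_components(g)]


def oracle_srf_core(peaks_by_sample, stringent_p):
    pool = []
    for label, peaks in peaks_by_sample.items():
        for p in peaks:
            if p.pvalue < stringent_p:
                p.sample = label
                pool.append(p)
    out = []
    for cluster in brute_clusters(pool):
        s = {p.sample for p in cluster}
        if ({"resting1", "resting2"} <= s or {"stim1", "stim2"} <= s
                or ("LatB" in s and len(s) > 1)
                or ("U0126" in s and len(s) > 1)):
            out.append(cluster)
    return out


def oracle_mrtf_primary(peaks, stringent_p):
    pool = [p for p in peaks if p.pvalue < stringent_p]
    out = []
    for cluster in brute_clusters(pool):
        by_ab, by_cond = {}, {}
        for p in cluster:
            by_ab.setdefault(p.antibody, set()).add(p.sample)
            by_cond.setdefault(p.condition, set()).add(p.antibody)
        if any(len(v) > 1 for v in by_ab.values()) or \
                any(v >= {"MRTF-A", "MRTF-B"} for v in by_cond.values()):
            out.append(cluster)
    return out


def oracle_tcf(peaks, stringent_p):
    pool = [p for p in peaks if p.pvalue < stringent_p]
    out = []
    for cluster in brute_clusters(pool):
        by_member, by_cond = {}, {}
        for p in cluster:
            by_member.setdefault(p.antibody, set()).add(p.condition)
            by_cond.setdefault(p.condition, set()).add(p.antibody)
        if any(len(v) > 1 for v in by_member.values()) or \
                any(len(v) > 1 for v in by_cond.values()):
            out.append(cluster)
    return out


def random_srf_fixture(rng, n_peaks):
    by = {lab: [] for lab in SRF_LABELS}
    for i in range(n_peaks):
        lab = SRF_LABELS[rng.integers(len(SRF_LABELS))]
        start = int(rng.integers(0, 3000))
        by[lab].append(make_peak(
            chrom=f"chr{rng.integers(1, 3)}", start=start,
            end=start + int(rng.integers(50, 300)),
            pvalue=float(10.0 ** -rng.uniform(0, 12)), name=f"p{i}",
            sample=lab))
    return by


def site_key(site_or_cluster):
    if isinstance(site_or_cluster, Site):
        return (site_or_cluster.chrom, site_or_cluster.interval.start,
                site_or_cluster.interval.end)
    start = min(p.interval.start for p in site_or_cluster)
    end = max(p.interval.end for p in site_or_cluster)
    return (site_or_cluster[0].chrom, start, end)


# ---------------------------------------------------------------------- tests

class TestClusterPeaks:
    def test_chained_overlaps_merge_transitively(self):
        a = make_peak(start=100, end=200)
        b = make_peak(start=180, end=300)
        c = make_peak(start=280, end=400)  # overlaps b, not a
        (cluster,) = cluster_peaks([a, b, c])
        assert len(cluster) == 3


class TestSrfCore:
    def test_resting_pair_included(self):
        by = {lab: [] for lab in SRF_LABELS}
        by["resting1"] = [make_peak(start=100, end=300, sample="resting1")]
        by["resting2"] = [make_peak(start=150, end=350, sample="resting2")]
        sites = call_srf_core(by)
        assert len(sites) == 1
        assert {s for s, _ in sites[0].evidence} == {"resting1", "resting2"}

    def test_single_stim_sample_excluded(self):
        by = {lab: [] for lab in SRF_LABELS}
        by["stim1"] = [make_peak(start=100, end=300, sample="stim1")]
        assert call_srf_core(by) == []

    def test_inhibitor_plus_any_other_included(self):
        by = {lab: [] for lab in SRF_LABELS}
        by["LatB"] = [make_peak(start=100, end=300, sample="LatB")]
        by["stim1"] = [make_peak(start=200, end=400, sample="stim1")]
        assert len(call_srf_core(by)) == 1

    def test_missing_sample_label_is_an_error(self):
        with pytest.raises(KeyError, match="U0126"):
            call_srf_core({lab: [] for lab in SRF_LABELS[:-1]})

    def test_summit_is_lowest_p_contributor(self):
        by = {lab: [] for lab in SRF_LABELS}
        by["resting1"] = [make_peak(start=100, end=300, summit=50,
                                    pvalue=1e-6, sample="resting1")]
        by["resting2"] = [make_peak(start=150, end=350, summit=120,
                                    pvalue=1e-9, sample="resting2")]
        (site,) = call_srf_core(by)
        assert site.summit == 150 + 120

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            by = random_srf_fixture(rng, int(rng.integers(5, 60)))
            got = {site_key(s) for s in call_srf_core(by)}
            want = {site_key(c) for c in oracle_srf_core(by, 1e-5)}
            assert got == want


class TestRescueSrf:
    def _site(self, start, end, family="SRF"):
        return Site(make_peak(start=start, end=end).interval,
                    (start + end) // 2, family, [("x", 1e-9)])

    def test_rescued_when_all_conditions_met(self):
        cand = [make_peak(start=1000, end=1200, pvalue=1e-3)]
        mrtf = [make_peak(start=1050, end=1250, pvalue=1e-9,
                          antibody="MRTF-B")]
        out = rescue_srf(cand, [], mrtf, lambda s: 2.4, lambda s: 0.4)
        assert len(out) == 1 and out[0].rescued
        assert out[0].rescue_rule == "mrtf_inducible_latB"

    def test_not_rescued_without_mrtf_overlap(self):
        cand = [make_peak(start=1000, end=1200, pvalue=1e-3)]
        assert rescue_srf(cand, [], [], lambda s: 2.4, lambda s: 0.4) == []

    def test_not_rescued_above_low_threshold(self):
        cand = [make_peak(start=1000, end=1200, pvalue=0.2)]
        mrtf = [make_peak(start=1050, end=1250, pvalue=1e-9)]
        assert rescue_srf(cand, [], mrtf, lambda s: 2.4, lambda s: 0.4) == []

    def test_not_rescued_without_inducibility_or_latB(self):
        cand = [make_peak(start=1000, end=1200, pvalue=1e-3)]
        mrtf = [make_peak(start=1050, end=1250, pvalue=1e-9)]
        assert rescue_srf(cand, [], mrtf, lambda s: 1.1, lambda s: 0.4) == []
        assert rescue_srf(cand, [], mrtf, lambda s: 2.4, lambda s: 0.9) == []

    def test_disjoint_from_core(self):
        core = [self._site(900, 1300)]
        cand = [make_peak(start=1000, end=1200, pvalue=1e-3)]
        mrtf = [make_peak(start=1050, end=1250, pvalue=1e-9)]
        assert rescue_srf(cand, core, mrtf,
                          lambda s: 2.4, lambda s: 0.4) == []


class TestMrtf:
    def _p(self, ab, cond, start=100, end=300, pvalue=1e-9):
        return make_peak(start=start, end=end, pvalue=pvalue,
                         sample=f"{ab}_{cond}", antibody=ab, condition=cond)

    def test_one_antibody_two_samples_rule(self):
        sites = call_mrtf([ ], [self._p("MRTF-B", "stimulated"),
                               self._p("MRTF-B", "LatB", start=150, end=350)],
                          [])
        assert len(sites) == 1 and sites[0].label == "B-only"

    def test_both_antibodies_same_condition_rule(self):
        sites = call_mrtf([self._p("MRTF-A", "stimulated")],
                          [self._p("MRTF-B", "stimulated", start=150,
                                   end=350)], [])
        assert len(sites) == 1 and sites[0].label == "A+B"

    def test_single_peak_needs_srf_rescue(self):
        lone = self._p("MRTF-B", "stimulated", pvalue=1e-3)
        assert call_mrtf([], [lone], []) == []
        srf = Site(make_peak(start=150, end=350).interval, 250, "SRF",
                   [("x", 1e-9)])
        sites = call_mrtf([], [lone], [srf])
        assert len(sites) == 1 and sites[0].rescued

    def test_matches_brute_force_oracle(self, rng):
        conds = ("resting", "stimulated", "LatB", "U0126")
        for _ in range(25):
            peaksA, peaksB = [], []
            for i in range(int(rng.integers(5, 50))):
                ab = "MRTF-A" if rng.random() < 0.5 else "MRTF-B"
                cond = conds[rng.integers(4)]
                start = int(rng.integers(0, 3000))
                p = make_peak(start=start,
                              end=start + int(rng.integers(50, 300)),
                              pvalue=float(10.0 ** -rng.uniform(0, 12)),
                              sample=f"{ab}_{cond}", antibody=ab,
                              condition=cond, name=f"p{i}")
                (peaksA if ab == "MRTF-A" else peaksB).append(p)
            got = {site_key(s)
                   for s in call_mrtf(peaksA, peaksB, [], low_p=1e-99)}
            want = {site_key(c)
                    for c in oracle_mrtf_primary(peaksA + peaksB, 1e-5)}
            assert got == want


class TestTcf:
    def _p(self, member, cond, start=100, end=300, pvalue=1e-9):
        return make_peak(start=start, end=end, pvalue=pvalue,
                         sample=f"{member}_{cond}", antibody=member,
                         condition=cond)

    def test_same_member_two_conditions(self):
        sites = call_tcf([self._p("Elk-1", "resting"),
                          self._p("Elk-1", "stimulated", start=150, end=350)])
        assert len(sites) == 1

    def test_two_members_same_condition(self):
        sites = call_tcf([self._p("Elk-1", "stimulated"),
                          self._p("Net", "stimulated", start=150, end=350)])
        assert len(sites) == 1 and sites[0].label == "Elk-1+Net"

    def test_single_member_single_condition_excluded(self):
        assert call_tcf([self._p("SAP-1", "stimulated")]) == []

    def test_matches_brute_force_oracle(self, rng):
        members = ("SAP-1", "Elk-1", "Net")
        conds = ("resting", "stimulated", "LatB", "U0126")
        for _ in range(25):
            peaks = []
            for i in range(int(rng.integers(5, 60))):
                start = int(rng.integers(0, 3000))
                peaks.append(self._p(
                    members[rng.integers(3)], conds[rng.integers(4)],
                    start=start, end=start + int(rng.integers(50, 300)),
                    pvalue=float(10.0 ** -rng.uniform(0, 12))))
            got = {site_key(s) for s in call_tcf(peaks)}
            want = {site_key(c) for c in oracle_tcf(peaks, 1e-5)}
            assert got == want
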