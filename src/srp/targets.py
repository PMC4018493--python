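"""Site-to-gene assignment, the 70-kb rule, and target gene sets.

A binding site is linked to its nearest gene by summit-to-feature
distance: distance 0 ("direct") when the summit lies within 2 kb of the
5' flanking sequence or inside any gene feature; "near" when within
70 kb of the TSS or pA site; "distal" otherwise.  Serum-inducible genes
with a direct or near SRF site form the SRF target set; MRTF candidates
add MRTF binding or actin-drug sensitivity; the stringent MRTF tier
requires both; TCF targets require TCF binding plus U0126 sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel


@dataclass
class TargetSets:
    """Nested target-gene sets (stringent subset chains are enforced)."""

    srf_targets: set[str]
    mrtf_candidates: set[str]
    mrtf_stringent: set[str]
    tcf_targets: set[str]

    def __post_init__(self) -> None:
        if not (self.mrtf_stringent <= self.mrtf_candidates
                <= self.srf_targets):
            raise ValueError("target-set inclusion chain violated")
        if not self.tcf_targets <= self.srf_targets:
            raise ValueError("TCF targets must be SRF targets")

    def sizes(self) -> dict[str, int]:
        return {
            "srf_targets": len(self.srf_targets),
            "mrtf_candidates": len(self.mrtf_candidates),
            "mrtf_stringent": len(self.mrtf_stringent),
            "tcf_targets": len(self.tcf_targets),
        }


def _gene_arrays(genes: Sequence[GeneModel]):
    per_chrom: dict[str, dict] = {}
    for g in genes:
        d = per_chrom.setdefault(g.interval.chrom, {
            "id": [], "start": [], "end": [], "tss": [], "pA": [],
            "strand": []})
        d["id"].append(g.id)
        d["start"].append(g.interval.start)
        d["end"].append(g.interval.end)
        d["tss"].append(g.tss)
        d["pA"].append(g.pA)
        d["strand"].append(g.strand)
    for d in per_chrom.values():
        for k in ("start", "end", "tss", "pA"):
            d[k] = np.asarray(d[k])
        d["id"] = np.asarray(d["id"])
        d["strand"] = np.asarray(d["strand"])
    return per_chrom


def _distances(summit: int, d: dict, promoter_bp: int) -> np.ndarray:
    """Summit-to-gene distance for every gene on the chromosome (0 = direct)."""
    inside = (d["start"] <= summit) & (summit < d["end"])
    plus = d["strand"] == "+"
    in_prom = np.where(
        plus,
        (d["tss"] - promoter_bp <= summit) & (summit < d["tss"]),
        (d["tss"] < summit) & (summit <= d["tss"] + promoter_bp),
    )
    dist = np.minimum(np.abs(summit - d["tss"]), np.abs(summit - d["pA"]))
    dist[inside | in_prom] = 0
    return dist


def link_sites_to_genes(
    sites: Sequence,
    genes: Sequence[GeneModel],
    near_bp: int = 70_000,
    promoter_bp: int = 2_000,
) -> pd.DataFrame:
    """Primary nearest-gene link per site with relation class and sharing.

    ``sites`` need ``id``, ``chrom`` and ``summit_pos``.  Ties on
    distance go to the gene earlier in genome order (deterministic).
    ``shared`` marks sites with a second gene within ``near_bp``; the
    count of such secondary genes is reported.
    """
    per_chrom = _gene_arrays(genes)
    rows = []
    for site in sites:
        d = per_chrom.get(site.chrom)
        if d is None or len(d["id"]) == 0:
            rows.append({"site_id": site.id, "gene_id": None,
                         "distance": np.inf, "relation": "distal",
                         "shared": False, "n_genes_within_near": 0})
            continue
        summit = site.summit_pos
        dist = _distances(summit, d, promoter_bp)
        order = np.argsort(d["start"], kind="mergesort")
        best = order[np.argmin(dist[order], )]
        best_dist = int(dist[best])
        relation = ("direct" if best_dist == 0
                    else "near" if best_dist <= near_bp
                    else "distal")
        within = int((dist <= near_bp).sum())
        rows.append({
            "site_id": site.id,
            "gene_id": d["id"][best],
            "distance": best_dist,
            "relation": relation,
            "shared": within > 1,
            "n_genes_within_near": within,
        })
    return pd.DataFrame(rows).set_index("site_id")


def distance_enrichment(
    sites: Sequence,
    active: Sequence[GeneModel],
    inactive: Sequence[GeneModel],
    bin_bp: int = 10_000,
    max_bp: int = 200_000,
    promoter_bp: int = 2_000,
) -> dict:
    """Site frequency by distance to active vs inactive genes, with tests.

    Per gene class, each site contributes its distance to the nearest
    gene of that class; the histogram uses ``bin_bp`` bins (bin 0 =
    direct).  A two-sided rank-sum test compares the distance
    distributions, and Fisher's exact test compares in-feature counts.
    """
    out = {}
    dists = {}
    for name, genes in (("active", active), ("inactive", inactive)):
        per_chrom = _gene_arrays(genes)
        vals = []
        for site in sites:
            d = per_chrom.get(site.chrom)
            if d is None:
                vals.append(np.inf)
                continue
            vals.append(float(_distances(site.summit_pos, d,
                                         promoter_bp).min()))
        dists[name] = np.asarray(vals)
    edges = np.arange(0, max_bp + bin_bp, bin_bp)
    hist = pd.DataFrame({
        name: np.histogram(v[np.isfinite(v)], bins=edges)[0]
        for name, v in dists.items()
    }, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    finite_a = dists["active"][np.isfinite(dists["active"])]
    finite_i = dists["inactive"][np.isfinite(dists["inactive"])]
    out["hist"] = hist
    out["rank_sum_p"] = float(stats.mannwhitneyu(
        finite_a, finite_i, alternative="two-sided").pvalue) \
        if len(finite_a) and len(finite_i) else np.nan
    in_a = int((dists["active"] == 0).sum())
    in_i = int((dists["inactive"] == 0).sum())
    n = len(dists["active"])
    table = [[in_a, n - in_a], [in_i, n - in_i]]
    out["fisher_table"] = table
    out["fisher_p"] = float(stats.fisher_exact(table)[1])
    return out


def define_target_sets(
    links: pd.DataFrame,
    serum_class: pd.Series,
    pathway_flags: pd.DataFrame,
    cofactor_class: pd.Series,
) -> TargetSets:
    """Target-gene sets from links, response classes and cofactor calls.

    ``links`` is the output of link_sites_to_genes for the SRF site set;
    ``cofactor_class`` maps SRF site id -> {MRTF, TCF, both, solo}.
    """
    linked = links[links["relation"].isin(["direct", "near"])]
    genes_with_site = set(linked["gene_id"].dropna())
    mrtf_linked = set(
        linked.loc[cofactor_class.reindex(linked.index)
                   .isin(["MRTF", "both"]), "gene_id"].dropna())
    tcf_linked = set(
        linked.loc[cofactor_class.reindex(linked.index)
                   .isin(["TCF", "both"]), "gene_id"].dropna())

    inducible = set(serum_class.index[serum_class == "inducible"])
    latB = set(pathway_flags.index[pathway_flags["latB_impaired"]])
    cd = set(pathway_flags.index[pathway_flags["cd_inducible"]])
    u0126 = set(pathway_flags.index[pathway_flags["u0126_impaired"]])

    srf_targets = inducible & genes_with_site
    mrtf_candidates = srf_targets & (mrtf_linked | latB | cd)
    mrtf_stringent = srf_targets & mrtf_linked & (latB | cd)
    tcf_targets = srf_targets & tcf_linked & u0126
    return TargetSets(srf_targets, mrtf_candidates, mrtf_stringent,
                      tcf_targets)


def signature_overlap(
    setA: set[str], setB: set[str], universe: set[str]
) -> dict:
    """Two-sided Fisher exact test on a 2x2 membership table.

    Fold enrichment is observed/expected overlap given independent draws
    from the universe.
    """
    A, B = setA & universe, setB & universe
    both = len(A & B)
    only_a = len(A) - both
    only_b = len(B) - both
    neither = len(universe) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    expected = len(A) * len(B) / len(universe) if universe else np.nan
    fold = both / expected if expected else np.nan
    return {"p": float(p), "odds_ratio": float(odds),
            "fold_enrichment": float(fold), "table": table,
            "overlap": both}
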