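"""Synthetic serum-response study generator with planted ground truth.

Emulates the structure of a fibroblast serum-response experiment: a toy
genome with gene models, planted SRF/MRTF/TCF binding sites carrying
CArG boxes, per-sample ChIP-seq peak calls over conditions
{resting (0.3% FCS), stimulated (15% FCS), LatB, U0126, CD}, ChIP signal
tracks, Pol II tracks for three CTD antibody classes, H3 nucleosome
tracks, and total+intronic RNA-seq count tables — together with a
TruthTable recording every planted label so recovery can be scored.

Design points (see docs/methods.md for rationale):

* Constitutive sites have mean binding inducibility 1.0, inducible sites
  2.5; inducible non-TCF sites lose signal under LatB (multiplier 0.4 on
  the stimulated level), inducible TCF sites under U0126.
* ChIP counts are negative binomial around the expected per-site signal;
  the simulated peak caller computes a Poisson p-value against a
  bead-control background rate, so weakly bound sites produce realistic
  borderline calls (P just under 0.05) that exercise the rescue rules.
* Every sample is "sequenced" to a nominal depth with a per-sample
  lognormal depth factor; counts, background and the recorded library
  size scale together, so library-size normalization must (and does)
  cancel it.
* All draws come from one numpy Generator: the same seed reproduces
  every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval, Peak, SignalTrack
from .motif_scan import CARG_CONSENSUS, scan_iupac

SRF_SAMPLES = (
    ("resting1", "resting"), ("resting2", "resting"),
    ("stim1", "stimulated"), ("stim2", "stimulated"),
    ("LatB", "LatB"), ("U0126", "U0126"),
)
MRTF_CONDITIONS = ("resting", "stimulated", "LatB", "U0126")
TCF_MEMBERS = ("SAP-1", "Elk-1", "Net")
RNA_CONDITIONS = ("resting", "stimulated", "LatB", "U0126", "CD")


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic serum-response experiment."""

    seed: int = 0

    # genome & gene models
    n_chroms: int = 4
    chrom_length: int = 2_500_000
    desert_length: int = 1_250_000  # gene-free tail of the last chromosome
    n_genes: int = 2000
    n_long_genes: int = 10       # 80-120 kb, exercise the +70 kb rule
    n_medium_genes: int = 140    # 10-40 kb, used for Pol II metaprofiles

    # gene response labels
    n_inducible_mrtf: int = 180
    n_inducible_tcf: int = 40
    n_inducible_other: int = 80
    n_repressed: int = 60
    frac_inactive: float = 0.30

    # planted binding sites per (inducibility class, cofactor class)
    site_counts: dict = field(default_factory=lambda: {
        ("inducible", "MRTF"): 280,
        ("inducible", "both"): 20,
        ("inducible", "TCF"): 30,
        ("inducible", "solo"): 70,
        ("constitutive", "MRTF"): 40,
        ("constitutive", "TCF"): 60,
        ("constitutive", "both"): 10,
        ("constitutive", "solo"): 70,
        ("constitutive", "MRTF-orphan"): 20,
    })
    n_weak_srf: int = 30   # low-SRF-signal sites that only the rescue rule finds
    n_distal_solo: int = 10     # constitutive solo sites >70 kb from any gene
    n_distal_orphan: int = 10

    # binding inducibility
    mean_inducibility: dict = field(default_factory=lambda: {
        "constitutive": 1.0, "inducible": 2.5})
    constitutive_sd: float = 0.08
    inducible_sigma_log: float = 0.22
    latB_effect: float = 0.4
    u0126_effect: float = 0.4

    # ChIP counts / peak calling
    chip_baseline_mean: float = 300.0
    chip_baseline_sigma_log: float = 0.6
    weak_baseline: float = 15.5
    chip_dispersion: float = 0.02
    chip_depth: float = 1e6          # nominal mapped reads per sample
    depth_jitter_sigma: float = 0.1  # lognormal per-sample depth factor
    ip_background_rate: float = 0.004  # IP background reads per bp
    control_lambda: float = 25.0     # bead-control reads per peak window
    peak_halfwidth: int = 150
    summit_jitter: float = 8.0
    kernel_sigma: float = 75.0
    n_noise_peaks: int = 20
    mrtf_baseline_mean: float = 300.0
    mrtfA_efficiency: tuple = (0.05, 0.7)
    mrtf_condition_factors: dict = field(default_factory=lambda: {
        "resting": 0.05, "stimulated": 1.0, "LatB": 0.05, "U0126": 0.8})
    tcf_baseline_mean: float = 250.0
    tcf_condition_factors: dict = field(default_factory=lambda: {
        "resting": 1.0, "stimulated": 1.1, "LatB": 1.05, "U0126": 0.8})

    # CArG boxes: P(best match = perfect, 1mm, 2mm, none) per class
    carg_mismatch_distribution: dict = field(default_factory=lambda: {
        "inducible": (0.60, 0.30, 0.08, 0.02),
        "constitutive": (0.30, 0.35, 0.20, 0.15),
    })

    # RNA-seq
    rnaseq_baseline_mean: float = 150.0
    rnaseq_baseline_sigma_log: float = 0.8
    inactive_baseline: float = 0.3
    fc_mean: float = 4.0
    fc_sigma_log: float = 0.25
    repressed_fc: float = 0.3
    total_damp: float = 0.7       # mature-RNA response relative to intronic
    intronic_fraction: float = 0.3
    latB_residual: float = 0.1    # induction remaining under LatB (MRTF genes)
    u0126_residual: float = 0.1
    frac_cd_inducible: float = 0.85
    cd_factor: float = 0.8
    rnaseq_dispersion: float = 0.05
    n_reps_rnaseq: int = 2
    scale_factors: dict = field(default_factory=lambda: {
        "resting": 1.0, "stimulated": 1.25, "LatB": 0.8,
        "U0126": 1.15, "CD": 0.9})

    # Pol II
    frac_group_I: float = 0.45
    promoter_reduction_I: tuple = (0.45, 0.75)
    promoter_reduction_II: tuple = (0.0, 0.15)
    polii_promoter_reads: float = 3000.0
    polii_sigma: float = 300.0
    polii_induction: float = 4.0
    polii_body_frac: float = 1.0   # body reads as a fraction of promoter reads
    polii_latB_body: float = 0.35
    polii_progress_bp: int = 70_000
    polii_depth: float = 1e7

    # H3
    h3_base_density: float = 0.1
    h3_dip_sigma: float = 100.0
    h3_dip_depth: dict = field(default_factory=lambda: {
        "constitutive": {"resting": 0.55, "stimulated": 0.55, "LatB": 0.55},
        "inducible": {"resting": 0.25, "stimulated": 0.60, "LatB": 0.25},
    })

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 200_000:
            raise ValueError("genome too small")
        if self.desert_length >= self.chrom_length:
            raise ValueError("desert longer than a chromosome")
        for v in (self.frac_inactive, self.frac_cd_inducible,
                  self.latB_effect, self.u0126_effect):
            if not 0 <= v <= 1:
                raise ValueError("probabilities/effects must be in [0, 1]")
        if any(n < 0 for n in self.site_counts.values()):
            raise ValueError("site counts must be >= 0")
        for dist in self.carg_mismatch_distribution.values():
            if abs(sum(dist) - 1) > 1e-9:
                raise ValueError("CArG mismatch distribution must sum to 1")

    @property
    def n_sites(self) -> int:
        return sum(self.site_counts.values())

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class TruthTable:
    """Planted labels for every site and gene, plus condition scale factors."""

    sites: pd.DataFrame
    genes: pd.DataFrame
    scale_factors: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        pd.Series(self.scale_factors).to_csv(
            outdir / "truth_scale_factors.tsv", sep="\t", header=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        sites = pd.read_csv(outdir / "truth_sites.tsv", sep="\t")
        genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t")
        sf = pd.read_csv(outdir / "truth_scale_factors.tsv", sep="\t",
                         header=None, index_col=0)[1].to_dict()
        return cls(sites, genes, sf)


# ---------------------------------------------------------------------------
# genome + gene models + site placement
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _nb_draw(rng: np.random.Generator, mu, phi: float):
    """Negative binomial with mean mu and dispersion phi (var = mu + phi mu^2).

    phi = 0 means a noise-free draw: counts equal the rounded mean.
    """
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return np.round(mu).astype(np.int64)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    r = 1.0 / phi
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p) if np.isscalar(p) else \
        rng.negative_binomial(r, p, size=p.shape)
    return out


def _draw_gene_lengths(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, size_class) with size_class in {short, medium, long}."""
    n_short = cfg.n_genes - cfg.n_long_genes - cfg.n_medium_genes
    if n_short < 0:
        raise ValueError("n_genes smaller than the medium+long gene count")
    long_l = rng.integers(80_000, 110_000, size=cfg.n_long_genes)
    med_l = rng.integers(10_000, 30_000, size=cfg.n_medium_genes)
    short_l = np.clip(
        rng.lognormal(np.log(1000), 0.5, size=n_short), 300, 5000
    ).astype(np.int64)
    lengths = np.concatenate([long_l, med_l, short_l])
    size_class = np.array(
        ["long"] * cfg.n_long_genes + ["medium"] * cfg.n_medium_genes
        + ["short"] * n_short)
    return lengths, size_class


def _make_exons(chrom, start, end, strand, rng) -> list[GenomicInterval]:
    L = end - start
    n_exons = 1 if L < 600 else int(rng.integers(1, min(6, L // 400) + 1))
    if n_exons == 1:
        return [GenomicInterval(chrom, start, end, strand)]
    cuts = np.sort(rng.choice(
        np.arange(100, L - 100), size=2 * (n_exons - 1), replace=False))
    bounds = np.concatenate([[0], cuts, [L]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, start + s, start + e, strand))
    return exons or [GenomicInterval(chrom, start, end, strand)]


def _place_genes(cfg: SimConfig, lengths, size_class, rng):
    """Sequentially pack genes onto chromosomes with random inter-gene gaps.

    Medium/long genes usually get a large upstream gap so that "near"
    sites (2-70 kb from the nearest gene) can be planted beside them.
    Returns a gene table (positions, strand, upstream gap) or raises when
    the genome cannot hold the requested genes.
    """
    order = rng.permutation(cfg.n_genes)
    chroms = cfg.chrom_names
    limits = {c: cfg.chrom_length for c in chroms}
    limits[chroms[-1]] = cfg.chrom_length - cfg.desert_length
    rows = []
    ci = 0
    cursor = 1000
    prev_end = 0
    pending_big = False  # a minus-strand big gene asks for a gap after it
    for gi in order:
        L = int(lengths[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        # medium/long genes get a large gap on their TSS side so their
        # promoter windows and "near" placements stay uncrowded; a few
        # short genes do too
        big = size_class[gi] != "short"
        small_big = rng.random() < (0.06 if not big else 0.0)
        want_big_before = pending_big or ((big or small_big)
                                          and strand == "+")
        pending_big = (big or small_big) and strand == "-"
        if want_big_before:
            gap = int(rng.integers(5200, 7500))
        else:
            gap = int(100 + rng.exponential(350))
        while True:
            if ci >= len(chroms):
                raise ValueError(
                    "genome too small to place the requested genes")
            start = cursor + gap
            if start + L + 1000 <= limits[chroms[ci]]:
                break
            ci += 1
            cursor, prev_end = 1000, 0
        rows.append({
            "idx": int(gi), "chrom": chroms[ci], "start": start,
            "end": start + L, "strand": strand,
            "upstream_gap": start - prev_end,
            "size_class": size_class[gi],
        })
        prev_end = start + L
        cursor = prev_end
    df = pd.DataFrame(rows).sort_values("idx").reset_index(drop=True)
    df["gene_id"] = [f"gene{int(i):04d}" for i in df["idx"]]
    df = df.sort_values(["chrom", "start"])
    nxt = df.groupby("chrom")["upstream_gap"].shift(-1)
    df["downstream_gap"] = nxt.fillna(10_000).astype(int)
    df["tss_side_gap"] = np.where(df["strand"] == "+",
                                  df["upstream_gap"], df["downstream_gap"])
    return df.sort_index()


def _assign_gene_labels(cfg: SimConfig, gdf: pd.DataFrame, rng) -> pd.DataFrame:
    """Response/pathway labels; medium+long genes are MRTF-inducible."""
    n = len(gdf)
    response = np.full(n, "", dtype=object)
    pathway = np.full(n, "none", dtype=object)
    is_big = (gdf["size_class"] != "short").to_numpy()
    big_idx = np.flatnonzero(is_big)
    response[big_idx] = "inducible"
    pathway[big_idx] = "MRTF"
    short_idx = rng.permutation(np.flatnonzero(~is_big))
    k = 0

    def take(m):
        nonlocal k
        sel = short_idx[k:k + m]
        k += m
        return sel

    # short genes promoted to the MRTF quota are drawn from uncrowded
    # neighborhoods (large upstream gap, >=1 kb long) so that their
    # promoter windows are not contaminated by neighboring genes
    n_extra = max(cfg.n_inducible_mrtf - len(big_idx), 0)
    gap = gdf["tss_side_gap"].to_numpy()
    glen = (gdf["end"] - gdf["start"]).to_numpy()
    preferred = (gap >= 5200) & (glen >= 1000)
    short_idx = np.concatenate([
        short_idx[preferred[short_idx]], short_idx[~preferred[short_idx]]])
    extra_mrtf = take(n_extra)
    response[extra_mrtf] = "inducible"
    pathway[extra_mrtf] = "MRTF"
    short_idx = rng.permutation(short_idx[k:])
    k = 0
    sel = take(cfg.n_inducible_tcf)
    response[sel] = "inducible"
    pathway[sel] = "TCF"
    sel = take(cfg.n_inducible_other)
    response[sel] = "inducible"
    sel = take(cfg.n_repressed)
    response[sel] = "repressed"
    sel = take(int(cfg.frac_inactive * n))
    response[sel] = "inactive"
    response[response == ""] = "constitutive"

    gdf = gdf.copy()
    gdf["response"] = response
    gdf["pathway"] = pathway
    gdf["active"] = response != "inactive"
    return gdf


_RELATION_MIX = {
    "constitutive": (("promoter", 0.70), ("intragenic", 0.15), ("near", 0.15)),
    "inducible": (("promoter", 0.40), ("intragenic", 0.30), ("near", 0.30)),
}

_HOST_POOL = {
    ("inducible", "MRTF"): ("inducible", "MRTF"),
    ("inducible", "both"): ("inducible", "MRTF"),
    ("inducible", "TCF"): ("inducible", "TCF"),
    ("inducible", "solo"): ("inducible", "none"),
    ("constitutive", "MRTF"): ("constitutive", None),
    ("constitutive", "TCF"): ("constitutive", None),
    ("constitutive", "both"): ("constitutive", None),
    ("constitutive", "solo"): ("constitutive", None),
    ("constitutive", "MRTF-orphan"): ("constitutive", None),
}


def _plan_sites(cfg: SimConfig, gdf: pd.DataFrame, rng) -> pd.DataFrame:
    """Choose a class, host gene, relation and summit for every planted site."""
    pools: dict[tuple, np.ndarray] = {}
    for key, (resp, path) in _HOST_POOL.items():
        mask = gdf["response"] == resp
        if path is not None:
            mask &= gdf["pathway"] == path
        pools[key] = rng.permutation(np.flatnonzero(mask.to_numpy()))

    occupied: dict[str, list[int]] = {c: [] for c in cfg.chrom_names}

    def far_enough(chrom, pos, min_sep=400):
        return all(abs(pos - q) >= min_sep for q in occupied[chrom])

    # per-chromosome gene geometry for ambiguity checks: a planted site
    # must not fall inside another gene's feature or 2-kb promoter window,
    # which would make its nearest-gene assignment a coin toss
    geom = {}
    for c in cfg.chrom_names:
        sub = gdf[gdf["chrom"] == c]
        geom[c] = {
            "idx": sub.index.to_numpy(),
            "start": sub["start"].to_numpy(),
            "end": sub["end"].to_numpy(),
            "plus": (sub["strand"] == "+").to_numpy(),
        }

    def unambiguous(chrom, pos, host):
        d = geom[chrom]
        inside = (d["start"] <= pos) & (pos < d["end"])
        prom = np.where(
            d["plus"],
            (d["start"] - 2000 <= pos) & (pos < d["start"]),
            (d["end"] < pos) & (pos <= d["end"] + 2000))
        hit = (inside | prom) & (d["idx"] != host)
        return not hit.any()

    host_cursor = {k: 0 for k in pools}
    sites_per_host: dict[int, int] = {}

    def next_host(key, need_big_gap=False):
        pool = pools[key]
        for _ in range(len(pool) * 2):
            i = host_cursor[key] % len(pool)
            host_cursor[key] += 1
            g = int(pool[i])
            if sites_per_host.get(g, 0) >= 2:
                continue
            if need_big_gap and gdf.at[g, "upstream_gap"] < 5200:
                continue
            return g
        return None

    desert_chrom = cfg.chrom_names[-1]
    desert_start = cfg.chrom_length - cfg.desert_length
    rows = []
    counter = 0
    for (ind_class, cofactor), n_class in sorted(cfg.site_counts.items()):
        n_distal = 0
        if (ind_class, cofactor) == ("constitutive", "solo"):
            n_distal = min(cfg.n_distal_solo, n_class)
        if (ind_class, cofactor) == ("constitutive", "MRTF-orphan"):
            n_distal = min(cfg.n_distal_orphan, n_class)
        mix_names = [m[0] for m in _RELATION_MIX[ind_class]]
        mix_p = np.array([m[1] for m in _RELATION_MIX[ind_class]])
        for j in range(n_class):
            if j < n_distal:
                relation = "distal"
            else:
                relation = mix_names[int(rng.choice(len(mix_p), p=mix_p))]
            summit = host = None
            for _attempt in range(60):
                # degrade a crowded/unplaceable relation rather than fail:
                # the realized relation is what the TruthTable records.
                if _attempt == 15 and relation == "near":
                    relation = "promoter"
                if _attempt == 45 and relation == "promoter":
                    relation = "intragenic"
                if relation == "distal":
                    pos = int(rng.integers(
                        desert_start + cfg.polii_progress_bp + 2000,
                        cfg.chrom_length - 2000))
                    if far_enough(desert_chrom, pos):
                        summit, chrom, host = pos, desert_chrom, None
                        break
                    continue
                g = next_host((ind_class, cofactor),
                              need_big_gap=(relation == "near"))
                if g is None:
                    relation = "promoter"
                    continue
                grow = gdf.loc[g]
                chrom = grow["chrom"]
                if relation == "promoter":
                    gap = int(grow["upstream_gap"])
                    if grow["strand"] == "+":
                        hi = min(1500, gap - 150)
                        if hi < 150:
                            relation = "intragenic"
                            continue
                        pos = int(grow["start"] - rng.integers(150, hi + 1))
                    else:
                        # 5' flank of a minus-strand gene is beyond its end;
                        # stay within its own downstream gap is unknown, so
                        # plant just inside the 2 kb window past the end.
                        pos = int(grow["end"] + rng.integers(150, 1500))
                elif relation == "intragenic":
                    if grow["end"] - grow["start"] < 600:
                        relation = "promoter"
                        continue
                    pos = int(rng.integers(grow["start"] + 150,
                                           grow["end"] - 150))
                else:  # near
                    gap = int(grow["upstream_gap"])
                    hi = min(gap // 2 - 100, 60_000)
                    if hi < 2300:
                        relation = "promoter"
                        continue
                    pos = int(grow["start"] - rng.integers(2300, hi + 1))
                # prefer positions whose nearest gene is unambiguously the
                # host; after enough failures accept an ambiguous spot (a
                # realistic residual: bidirectional promoters exist)
                if 1500 < pos < cfg.chrom_length - 1500 and \
                        far_enough(chrom, pos) and \
                        (relation == "near" or _attempt >= 25
                         or unambiguous(chrom, pos, g)):
                    summit, host = pos, g
                    break
            if summit is None:
                raise ValueError("could not place all requested sites; "
                                 "genome too small or too crowded")
            occupied[chrom].append(summit)
            if host is not None:
                sites_per_host[host] = sites_per_host.get(host, 0) + 1
            rows.append({
                "site_id": f"site{counter:04d}",
                "chrom": chrom, "summit": summit,
                "ind_class": ind_class, "cofactor": cofactor,
                "relation": relation,
                "host_gene": gdf.at[host, "gene_id"] if host is not None
                else "",
            })
            counter += 1
    return pd.DataFrame(rows)


_CARG_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _embed_carg(codes: np.ndarray, summit: int, planted_m: int,
                rng: np.random.Generator) -> bool:
    """Embed a CArG 10-mer with exactly ``planted_m`` best-match mismatches
    within 100 bp of the summit; planted_m = -1 means a window with no
    match at <=2 mismatches.  Returns True on success."""
    lo, hi = summit - 100, summit + 100
    if lo < 0 or hi > codes.size:
        return False
    for _try in range(200):
        codes[lo:hi] = rng.integers(0, 4, size=hi - lo)
        if planted_m >= 0:
            motif = np.empty(10, dtype=codes.dtype)
            motif[[0, 1]] = 1          # C C
            motif[[8, 9]] = 2          # G G
            motif[2:8] = rng.choice([0, 3], size=6)   # W = A or T
            if planted_m > 0:
                pos = rng.choice(10, size=planted_m, replace=False)
                for p in pos:
                    if 2 <= p <= 7:
                        motif[p] = rng.choice([1, 2])          # violate W
                    elif p <= 1:
                        motif[p] = rng.choice([0, 2, 3])       # violate C
                    else:
                        motif[p] = rng.choice([0, 1, 3])       # violate G
            start = int(rng.integers(lo, hi - 10))
            codes[start:start + 10] = motif
        window = _decode(codes[lo:hi])
        hits = scan_iupac(window, CARG_CONSENSUS, max_mismatch=2)
        best = min((h.mismatches for h in hits), default=-1)
        if planted_m == -1 and best == -1:
            return True
        if planted_m >= 0 and best == planted_m:
            return True
    return False


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Toy genome, gene models and planted sites with a TruthTable.

    Deterministic under the config seed; raises if the genome cannot hold
    the requested genes/sites.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    lengths, size_class = _draw_gene_lengths(config, rng)
    gdf = _place_genes(config, lengths, size_class, rng)
    gdf = _assign_gene_labels(config, gdf, rng)
    sdf = _plan_sites(config, gdf, rng)

    # per-site planted parameters -----------------------------------------
    n = len(sdf)
    ind = (sdf["ind_class"] == "inducible").to_numpy()
    inducibility = np.where(
        ind,
        rng.lognormal(np.log(config.mean_inducibility["inducible"])
                      - config.inducible_sigma_log ** 2 / 2,
                      config.inducible_sigma_log, size=n),
        np.clip(rng.normal(config.mean_inducibility["constitutive"],
                           config.constitutive_sd, size=n), 0.5, None),
    )
    baseline = rng.lognormal(
        np.log(config.chip_baseline_mean)
        - config.chip_baseline_sigma_log ** 2 / 2,
        config.chip_baseline_sigma_log, size=n).clip(40, None)
    weak = np.zeros(n, dtype=bool)
    weak_pool = np.flatnonzero(
        ind & sdf["cofactor"].isin(["MRTF"]).to_numpy()
        & (sdf["relation"] != "distal").to_numpy())
    chosen = rng.choice(weak_pool, size=min(config.n_weak_srf, len(weak_pool)),
                        replace=False)
    weak[chosen] = True
    # weak sites must fail the stringent caller in every sample yet be
    # callable at P < 0.05 when stimulated: keep their baseline in the
    # narrow band that makes the rescue rule the only route in
    baseline[weak] = np.clip(
        rng.normal(config.weak_baseline, 1.0, size=weak.sum()),
        config.weak_baseline - 1.5, config.weak_baseline + 1.5)
    # and their induced signal sits between the low and stringent caller
    # cutoffs, so the rescue rule is their only route into the site set
    inducibility[weak] = np.clip(inducibility[weak], 2.2, 2.8)
    orphan = (sdf["cofactor"] == "MRTF-orphan").to_numpy()
    baseline[orphan] = 0.0

    mrtf_baseline = np.where(
        sdf["cofactor"].isin(["MRTF", "both", "MRTF-orphan"]),
        rng.lognormal(np.log(config.mrtf_baseline_mean) - 0.18, 0.6, size=n)
        .clip(60, None),
        0.0)
    tcf_baseline = np.where(
        sdf["cofactor"].isin(["TCF", "both"]),
        rng.lognormal(np.log(config.tcf_baseline_mean) - 0.18, 0.6, size=n)
        .clip(60, None),
        0.0)
    members = []
    for has in (tcf_baseline > 0):
        if not has:
            members.append("")
            continue
        k = int(rng.choice([1, 2, 3], p=[0.30, 0.45, 0.25]))
        members.append(",".join(sorted(
            rng.choice(TCF_MEMBERS, size=k, replace=False))))

    carg = np.full(n, -1, dtype=int)
    for cls, dist in config.carg_mismatch_distribution.items():
        mask = np.flatnonzero((sdf["ind_class"] == cls).to_numpy() & ~orphan)
        draws = rng.choice([0, 1, 2, -1], size=len(mask), p=list(dist))
        carg[mask] = draws

    sdf = sdf.assign(
        inducibility=inducibility, srf_baseline=baseline, weak_srf=weak,
        mrtf_baseline=mrtf_baseline, tcf_baseline=tcf_baseline,
        tcf_members=members, carg_mm=carg, orphan=orphan,
        start=sdf["summit"] - config.peak_halfwidth,
        end=sdf["summit"] + config.peak_halfwidth,
    )

    # sequence -------------------------------------------------------------
    genome: dict[str, str] = {}
    chrom_codes = {
        c: rng.integers(0, 4, size=config.chrom_length).astype(np.int8)
        for c in config.chrom_names
    }
    for row in sdf.itertuples():
        ok = _embed_carg(chrom_codes[row.chrom], int(row.summit),
                         int(row.carg_mm), rng)
        if not ok:
            raise RuntimeError(f"could not embed CArG at {row.site_id}")
    for c in config.chrom_names:
        genome[c] = _decode(chrom_codes[c].astype(np.uint8))

    # gene models ----------------------------------------------------------
    genes = []
    for row in gdf.itertuples():
        exons = _make_exons(row.chrom, int(row.start), int(row.end),
                            row.strand, rng)
        genes.append(GeneModel(row.gene_id,
                               GenomicInterval(row.chrom, int(row.start),
                                               int(row.end), row.strand),
                               exons))

    # per-gene RNA-seq / Pol II planted parameters -------------------------
    g = gdf.copy()
    g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"])
    g["pA"] = np.where(g["strand"] == "+", g["end"], g["start"])
    g["length"] = g["end"] - g["start"]
    base = rng.lognormal(
        np.log(config.rnaseq_baseline_mean)
        - config.rnaseq_baseline_sigma_log ** 2 / 2,
        config.rnaseq_baseline_sigma_log, size=len(g))
    base[~g["active"].to_numpy()] = config.inactive_baseline
    g["rnaseq_baseline"] = base
    fc = np.ones(len(g))
    indg = (g["response"] == "inducible").to_numpy()
    fc[indg] = rng.lognormal(np.log(config.fc_mean), config.fc_sigma_log,
                             size=indg.sum()).clip(2.0, None)
    fc[(g["response"] == "repressed").to_numpy()] = config.repressed_fc
    g["fc"] = fc
    g["latB_impaired"] = indg & (g["pathway"] == "MRTF").to_numpy()
    g["u0126_impaired"] = indg & (g["pathway"] == "TCF").to_numpy()
    g["cd_inducible"] = g["latB_impaired"] & (
        rng.random(len(g)) < config.frac_cd_inducible)

    group = np.full(len(g), "", dtype=object)
    red = np.zeros(len(g))
    cand = np.flatnonzero(g["latB_impaired"].to_numpy())
    is_I = rng.random(len(cand)) < config.frac_group_I
    lo1, hi1 = config.promoter_reduction_I
    lo2, hi2 = config.promoter_reduction_II
    group[cand[is_I]] = "I"
    group[cand[~is_I]] = "II"
    red[cand[is_I]] = rng.uniform(lo1, hi1, size=is_I.sum())
    red[cand[~is_I]] = rng.uniform(lo2, hi2, size=(~is_I).sum())
    g["polii_group"] = group
    g["promoter_reduction"] = red

    truth = TruthTable(
        sites=sdf.reset_index(drop=True),
        genes=g.drop(columns=["idx"]).reset_index(drop=True),
        scale_factors=dict(config.scale_factors),
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# ChIP-seq simulation
# ---------------------------------------------------------------------------

def _srf_condition_mu(row, cond: str, cfg: SimConfig) -> float:
    b, ratio = row.srf_baseline, row.inducibility
    if b == 0:
        return 0.0
    if cond == "resting":
        return b
    latB_sens = row.ind_class == "inducible" and \
        row.cofactor in ("MRTF", "both", "solo")
    u0126_sens = row.ind_class == "inducible" and row.cofactor == "TCF"
    if cond == "stimulated":
        return b * ratio
    if cond == "LatB":
        return b * ratio * (cfg.latB_effect if latB_sens else 1.0)
    if cond == "U0126":
        return b * ratio * (cfg.u0126_effect if u0126_sens else 1.0)
    raise ValueError(cond)


@dataclass
class ChipSim:
    """Per-sample peak calls, per-site count table, and signal tracks."""

    peaks: dict[str, list[Peak]]           # sample key -> peaks (P < 0.05)
    counts: pd.DataFrame                   # site x "antibody:sample" counts
    srf_tracks: dict[str, SignalTrack]     # condition -> pooled SRF track
    mrtf_tracks: dict[str, SignalTrack]    # condition -> pooled MRTF-A+B
    mrtfA_stim: SignalTrack
    mrtfB_stim: SignalTrack
    tcf_tracks: dict[str, SignalTrack]     # condition -> pooled TCF members


def _pvalue(k: np.ndarray, lam: float) -> np.ndarray:
    p = stats.poisson.sf(k - 1, lam)
    return np.clip(p, 1e-300, 1.0)


def _make_track(cfg, chrom_sizes, site_pos_by_chrom, site_reads_by_chrom,
                depth_factors, rng) -> SignalTrack:
    """Background + Gaussian read kernels at sites; one pooled track."""
    half = int(4 * cfg.kernel_sigma)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / cfg.kernel_sigma) ** 2)
    kernel /= kernel.sum()
    data = {}
    bg = cfg.ip_background_rate * sum(depth_factors)
    for chrom, L in chrom_sizes.items():
        arr = rng.poisson(bg, size=L).astype(np.float32)
        for pos, reads in zip(site_pos_by_chrom.get(chrom, ()),
                              site_reads_by_chrom.get(chrom, ())):
            lo, hi = pos - half, pos + half + 1
            klo, khi = max(0, -lo), len(kernel) - max(0, hi - L)
            arr[max(lo, 0):min(hi, L)] += (reads * kernel[klo:khi]).astype(
                np.float32)
        data[chrom] = arr
    lib = cfg.chip_depth * sum(depth_factors)
    return SignalTrack(data, library_size=lib)


def simulate_chip(
    truth: TruthTable, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ChipSim:
    """ChIP-seq peak calls, per-site counts and tracks for all antibodies.

    The expected per-site signal is baseline x inducibility(condition),
    times the LatB/U0126 effect where the site's pathway makes it
    sensitive; counts are NB; a peak is emitted in a sample iff the
    Poisson p-value against the bead-control background passes P < 0.05
    (callers downstream re-threshold at the stringent cutoff).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cfg = config
    sites = truth.sites
    chrom_sizes = {c: cfg.chrom_length for c in cfg.chrom_names}
    lam_win = cfg.ip_background_rate * 2 * cfg.peak_halfwidth

    peaks: dict[str, list[Peak]] = {}
    count_cols: dict[str, np.ndarray] = {}
    track_reads: dict[tuple, dict[str, np.ndarray]] = {}
    track_depths: dict[tuple, list[float]] = {}

    pos_by_chrom = {
        c: sites.loc[sites["chrom"] == c, "summit"].to_numpy()
        for c in cfg.chrom_names}
    idx_by_chrom = {
        c: np.flatnonzero((sites["chrom"] == c).to_numpy())
        for c in cfg.chrom_names}

    def run_sample(sample_key, antibody, condition, mu, family_track_keys):
        """Draw counts, call peaks, and accumulate per-track site reads."""
        d = float(rng.lognormal(0.0, cfg.depth_jitter_sigma))
        signal = _nb_draw(rng, mu * d, cfg.chip_dispersion)
        bg = rng.poisson(lam_win * d, size=len(mu))
        k = signal + bg
        pvals = _pvalue(k, cfg.control_lambda)
        plist = []
        for i in np.flatnonzero(pvals < 0.05):
            jitter = int(round(rng.normal(0, cfg.summit_jitter)))
            s = int(sites.at[i, "summit"]) + jitter
            iv = GenomicInterval(sites.at[i, "chrom"],
                                 s - cfg.peak_halfwidth,
                                 s + cfg.peak_halfwidth)
            plist.append(Peak(iv, cfg.peak_halfwidth,
                              min(1000.0, -10 * np.log10(pvals[i])),
                              float(pvals[i]), sample_key, antibody,
                              condition, f"{sample_key}_{i}"))
        # spurious single-sample peaks at random positions
        for _ in range(cfg.n_noise_peaks):
            chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
            pos = int(rng.integers(2000, cfg.chrom_length - 2000))
            kn = int(rng.integers(55, 90))
            pn = float(_pvalue(np.array([kn]), cfg.control_lambda)[0])
            iv = GenomicInterval(chrom, pos - cfg.peak_halfwidth,
                                 pos + cfg.peak_halfwidth)
            plist.append(Peak(iv, cfg.peak_halfwidth,
                              min(1000.0, -10 * np.log10(pn)), pn,
                              sample_key, antibody, condition, "noise"))
        plist.sort(key=lambda p: (p.chrom, p.interval.start))
        peaks[sample_key] = plist
        count_cols[f"{antibody}:{sample_key}"] = k
        for tkey in family_track_keys:
            acc = track_reads.setdefault(
                tkey, {c: np.zeros(len(idx_by_chrom[c])) for c in
                       cfg.chrom_names})
            for c in cfg.chrom_names:
                acc[c] += signal[idx_by_chrom[c]]
            track_depths.setdefault(tkey, []).append(d)

    # SRF ------------------------------------------------------------------
    for sample, cond in SRF_SAMPLES:
        mu = np.array([_srf_condition_mu(r, cond, cfg)
                       for r in sites.itertuples()])
        run_sample(f"SRF_{sample}", "SRF", cond, mu, [("SRF", cond)])

    # MRTF-A / MRTF-B ------------------------------------------------------
    effA = rng.uniform(*cfg.mrtfA_efficiency, size=len(sites))
    for cond in MRTF_CONDITIONS:
        f = cfg.mrtf_condition_factors[cond]
        muB = sites["mrtf_baseline"].to_numpy() * f
        muA = muB * effA
        keysA = [("MRTF", cond)] + ([("MRTF-A", "stimulated")]
                                    if cond == "stimulated" else [])
        keysB = [("MRTF", cond)] + ([("MRTF-B", "stimulated")]
                                    if cond == "stimulated" else [])
        run_sample(f"MRTF-A_{cond}", "MRTF-A", cond, muA, keysA)
        run_sample(f"MRTF-B_{cond}", "MRTF-B", cond, muB, keysB)

    # TCFs -----------------------------------------------------------------
    member_mult = {m: float(rng.lognormal(0, 0.3)) for m in TCF_MEMBERS}
    member_sets = [set(m.split(",")) if m else set()
                   for m in sites["tcf_members"]]
    for member in TCF_MEMBERS:
        present = np.array([member in s for s in member_sets])
        for cond in MRTF_CONDITIONS:
            f = cfg.tcf_condition_factors[cond]
            mu = sites["tcf_baseline"].to_numpy() * f * \
                member_mult[member] * present
            keys = [("TCF", cond)] if cond in ("resting", "stimulated") else []
            run_sample(f"{member}_{cond}", member, cond, mu, keys)

    # tracks ---------------------------------------------------------------
    def build(tkey):
        reads = track_reads[tkey]
        return _make_track(cfg, chrom_sizes, pos_by_chrom, reads,
                           track_depths[tkey], rng)

    srf_tracks = {c: build(("SRF", c)) for _, c in SRF_SAMPLES
                  if ("SRF", c) in track_reads}
    mrtf_tracks = {c: build(("MRTF", c)) for c in MRTF_CONDITIONS}
    tcf_tracks = {c: build(("TCF", c)) for c in ("resting", "stimulated")}
    counts = pd.DataFrame(count_cols, index=sites["site_id"])
    return ChipSim(peaks, counts, srf_tracks, mrtf_tracks,
                   build(("MRTF-A", "stimulated")),
                   build(("MRTF-B", "stimulated")), tcf_tracks)


def simulate_site_signals(
    n_constitutive: int, n_inducible: int, config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Direct draw of per-site condition signals (no genome, large n).

    Emulates what quantify_sites measures for a planted mixture of
    constitutive and inducible sites; used for threshold-recovery studies
    at sizes where a full genome would be wasteful.  Returns the signal
    table (same columns as quantify_sites) and the true class labels.
    """
    cfg = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 7)
    n = n_constitutive + n_inducible
    labels = pd.Series(["constitutive"] * n_constitutive
                       + ["inducible"] * n_inducible,
                       index=[f"s{i:05d}" for i in range(n)], name="truth")
    ind = labels.to_numpy() == "inducible"
    ratio = np.where(
        ind,
        rng.lognormal(np.log(cfg.mean_inducibility["inducible"])
                      - cfg.inducible_sigma_log ** 2 / 2,
                      cfg.inducible_sigma_log, size=n),
        np.clip(rng.normal(cfg.mean_inducibility["constitutive"],
                           cfg.constitutive_sd, size=n), 0.5, None))
    b = rng.lognormal(np.log(cfg.chip_baseline_mean)
                      - cfg.chip_baseline_sigma_log ** 2 / 2,
                      cfg.chip_baseline_sigma_log, size=n).clip(40, None)
    bg = cfg.ip_background_rate * 400  # per-rep background in the window
    reps = 2
    lat_sens = ind  # the inducible population is MRTF-driven here
    out = {}
    for cond, mult in (("resting", np.ones(n)), ("stimulated", ratio),
                       ("LatB", np.where(lat_sens, ratio * cfg.latB_effect,
                                         ratio)),
                       ("U0126", ratio)):
        total = np.zeros(n)
        for _ in range(reps):
            total = total + _nb_draw(rng, b * mult, cfg.chip_dispersion) \
                + rng.poisson(bg, size=n)
        out[cond] = total
    df = pd.DataFrame(out, index=labels.index)
    pc = 1.0
    df["inducibility"] = (df["stimulated"] + pc) / (df["resting"] + pc)
    df["latB_ratio"] = (df["LatB"] + pc) / (df["stimulated"] + pc)
    df["u0126_ratio"] = (df["U0126"] + pc) / (df["stimulated"] + pc)
    return df, labels


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def _rna_condition_factor(row, cond: str, cfg: SimConfig) -> float:
    """Intronic-read (pre-mRNA) fold change of a gene in a condition."""
    fc = row.fc
    if cond == "resting":
        return 1.0
    if cond == "stimulated":
        return fc
    if cond == "LatB":
        if row.latB_impaired:
            return 1.0 + (fc - 1.0) * cfg.latB_residual
        return fc
    if cond == "U0126":
        if row.u0126_impaired:
            return 1.0 + (fc - 1.0) * cfg.u0126_residual
        return fc
    if cond == "CD":
        if row.cd_inducible:
            return 1.0 + (fc - 1.0) * cfg.cd_factor
        return 1.0
    raise ValueError(cond)


def simulate_rnaseq(
    truth: TruthTable, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total and intronic count tables per condition/replicate.

    Intronic reads track the full planted fold change (pre-mRNA responds
    immediately); total reads respond with a damped fold change (mature
    RNA lags a 30-min stimulation).  Planted per-condition scale factors
    multiply every count of that condition's samples.  Returns
    (counts, meta): counts is genes x samples, meta maps each sample to
    (condition, replicate, read_class).
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    g = truth.genes
    cols, meta_rows = {}, []
    base = g["rnaseq_baseline"].to_numpy()
    for cond in RNA_CONDITIONS:
        f_int = np.array([_rna_condition_factor(r, cond, cfg)
                          for r in g.itertuples()])
        f_tot = 1.0 + (f_int - 1.0) * cfg.total_damp
        s = cfg.scale_factors[cond]
        for rep in range(1, cfg.n_reps_rnaseq + 1):
            for read_class, f in (("all", f_tot), ("intronic", f_int)):
                frac = 1.0 if read_class == "all" else cfg.intronic_fraction
                mu = base * f * s * frac
                name = f"{cond}_rep{rep}_{read_class}"
                cols[name] = _nb_draw(rng, mu, cfg.rnaseq_dispersion)
                meta_rows.append({"sample": name, "condition": cond,
                                  "replicate": rep,
                                  "read_class": read_class})
    counts = pd.DataFrame(cols, index=g["gene_id"])
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return counts, meta


# ---------------------------------------------------------------------------
# Pol II and H3 tracks
# ---------------------------------------------------------------------------

POLII_ANTIBODIES = ("8WG16", "H14", "H5")
POLII_CONDITIONS = ("resting", "stimulated", "LatB")


def simulate_polII(
    truth: TruthTable, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], SignalTrack]:
    """Pol II coverage per CTD antibody class and condition.

    Group I genes: promoter signal is serum-inducible and reduced by LatB
    by the planted fraction (>30%); group II genes: promoter signal is
    already present in resting cells and LatB-insensitive, while gene-body
    S5P/S2P signal remains LatB-sensitive in both groups.  Pol II
    progress is limited to +70 kb of the TSS after a 30-min stimulation.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    g = truth.genes
    means = {(ab, cond): {c: np.zeros(cfg.chrom_length, dtype=np.float64)
                          for c in cfg.chrom_names}
             for ab in POLII_ANTIBODIES for cond in POLII_CONDITIONS}

    half = int(3 * cfg.polii_sigma)
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / cfg.polii_sigma) ** 2)
    kern /= kern.sum()

    amp = cfg.polii_promoter_reads * rng.lognormal(0, 0.3, size=len(g))

    def add_gauss(arr, pos, mass):
        L = arr.size
        lo, hi = pos - half, pos + half + 1
        klo = max(0, -lo)
        khi = len(kern) - max(0, hi - L)
        arr[max(lo, 0):min(hi, L)] += mass * kern[klo:khi]

    def add_body(arr, lo, hi, mass):
        lo, hi = max(lo, 0), min(hi, arr.size)
        if hi > lo and mass > 0:
            arr[lo:hi] += mass / (hi - lo)

    for i, row in enumerate(g.itertuples()):
        if not row.active:
            continue
        P = amp[i]
        tss, pA, strand = int(row.tss), int(row.pA), row.strand
        sign = 1 if strand == "+" else -1
        body_end = tss + sign * min(abs(pA - tss), cfg.polii_progress_bp)
        inducible = row.response == "inducible"
        for cond in POLII_CONDITIONS:
            if row.polii_group == "I":
                prom = {"resting": P / cfg.polii_induction,
                        "stimulated": P,
                        "LatB": P * (1 - row.promoter_reduction)}[cond]
            elif row.polii_group == "II":
                prom = {"resting": P * 0.8, "stimulated": P,
                        "LatB": P * (1 - row.promoter_reduction)}[cond]
            elif inducible:
                prom = {"resting": P / cfg.polii_induction,
                        "stimulated": P, "LatB": P}[cond]
            else:
                prom = P * 0.6
            body = prom if not row.polii_group else {
                "resting": P / (2 * cfg.polii_induction),
                "stimulated": P,
                "LatB": P * cfg.polii_latB_body}[cond]
            body_mass = cfg.polii_body_frac * body
            lo, hi = sorted((tss + sign * 1000, body_end))
            arr = means[("8WG16", cond)][row.chrom]
            add_gauss(arr, tss, prom)
            add_body(arr, lo, hi, 0.15 * body_mass)
            arr = means[("H14", cond)][row.chrom]
            add_gauss(arr, tss, 0.6 * prom)
            add_body(arr, lo, hi, body_mass)
            arr = means[("H5", cond)][row.chrom]
            add_body(arr, lo, hi, body_mass)

    tracks = {}
    for key, per_chrom in means.items():
        data = {c: rng.poisson(per_chrom[c]).astype(np.float32)
                for c in cfg.chrom_names}
        tracks[key] = SignalTrack(data, library_size=cfg.polii_depth)
    return tracks


def simulate_h3(
    truth: TruthTable, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, SignalTrack]:
    """H3 nucleosome-occupancy tracks with planted dips at binding sites.

    Constitutive sites carry a condition-independent depletion; inducible
    sites are weakly depleted when resting, strongly depleted after
    stimulation, and revert under LatB (MRTF-dependent displacement).
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 4)
    half = int(3 * cfg.h3_dip_sigma)
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / cfg.h3_dip_sigma) ** 2)
    tracks = {}
    for cond in POLII_CONDITIONS:
        data = {}
        for chrom in cfg.chrom_names:
            mean = np.full(cfg.chrom_length, cfg.h3_base_density)
            sub = truth.sites[truth.sites["chrom"] == chrom]
            for row in sub.itertuples():
                depth = cfg.h3_dip_depth[row.ind_class][cond]
                pos = int(row.summit)
                lo, hi = pos - half, pos + half + 1
                klo = max(0, -lo)
                khi = len(kern) - max(0, hi - cfg.chrom_length)
                mean[max(lo, 0):min(hi, cfg.chrom_length)] -= \
                    depth * cfg.h3_base_density * kern[klo:khi]
            data[chrom] = rng.poisson(np.clip(mean, 0, None)).astype(
                np.float32)
        tracks[cond] = SignalTrack(data)
    return tracks


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTable
    chip: ChipSim
    rna_counts: pd.DataFrame
    rna_meta: pd.DataFrame
    polii_tracks: dict
    h3_tracks: dict


def simulate_all(config: SimConfig) -> SimulatedStudy:
    """Generate the complete synthetic study from one seed."""
    rng = np.random.default_rng(config.seed)
    genome, genes, truth = generate_genome(config, rng)
    chip = simulate_chip(truth, config, rng)
    rna_counts, rna_meta = simulate_rnaseq(truth, config, rng)
    polii = simulate_polII(truth, config, rng)
    h3 = simulate_h3(truth, config, rng)
    return SimulatedStudy(config, genome, genes, truth, chip,
                          rna_counts, rna_meta, polii, h3)
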