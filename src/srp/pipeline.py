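"""End-to-end orchestration: simulate -> consensus -> classify -> report.

Runs the whole serum-response analysis on a synthetic study and scores
recovery against the planted truth.  Stages communicate through a
context dict and can be skipped (downstream stages then fail with a
dependency error naming the missing stage).  The JSON report contains
site counts per class, the threshold fit, gene-set sizes, Pol II group
counts, and recovery metrics (sensitivity, precision, scale-factor
error, classification accuracies, H3 dip tests).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import cofactor as cf
from . import expression as ex
from . import inducibility as ind
from . import motif_scan as ms
from . import peak_consensus as pc
from . import polii_profiles as pp
from . import targets as tg
from .synthetic_data import SimConfig, simulate_all

STAGES = ("simulate", "srf", "mrtf", "tcf", "classify", "carg",
          "cofactor", "expression", "targets", "polii", "h3", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the study's stated values."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str | None = None

    stringent_p: float = 1e-5
    low_p: float = 0.05
    slop: int = 0
    window_bp: int = 400
    pseudocount: float = 1.0
    grid_start: float = 1.05
    grid_stop: float = 3.0
    grid_step: float = 0.01
    rescue_inducibility: float = 1.5
    latB_cut: float = 0.67
    u0126_cut: float = 0.67
    carg_window_bp: int = 200
    carg_budget: int = 2
    dominance_fold: float = 2.0
    norm_mode: str = "levels"
    fdr_serum: float = 0.2
    fdr_pathway: float = 0.08
    active_floor_per_kb: float = 1.0
    near_bp: int = 70_000
    promoter_bp: int = 2_000
    group_threshold: float = 0.30
    h3_half_width: int = 1_000
    h3_bin_bp: int = 8
    h3_normalize_to: float = 3e8
    match_bp: int = 200  # truth-matching tolerance for recovery scoring

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 1e-9,
                         self.grid_step)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["site_counts"] = {
            f"{k[0]}/{k[1]}": v for k, v in d["sim"]["site_counts"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        if "site_counts" in sim:
            sim["site_counts"] = {
                tuple(k.split("/")): v
                for k, v in sim["site_counts"].items()}
        return cls(sim=SimConfig(**sim), **d)


def _need(ctx: dict, key: str, stage: str, needed_by: str):
    if key not in ctx:
        raise PipelineError(
            f"stage '{needed_by}' requires output of stage '{stage}', "
            "which did not run")
    return ctx[key]


def _match_sites(called, truth_sites: pd.DataFrame, match_bp: int):
    """Map each called site to the nearest planted summit within match_bp.

    Returns (truth_index_per_called or -1, matched truth index set).
    """
    by_chrom = {
        c: sub for c, sub in truth_sites.groupby("chrom")}
    assign = []
    matched = set()
    for s in called:
        sub = by_chrom.get(s.chrom)
        idx = -1
        if sub is not None:
            d = (sub["summit"] - s.summit_pos).abs()
            j = d.idxmin()
            if d.loc[j] <= match_bp:
                idx = j
                matched.add(j)
        assign.append(idx)
    return np.array(assign), matched


def run_pipeline(config: RunConfig, skip: tuple[str, ...] = ()) -> dict:
    """Run all stages; returns the report dict (also written to outdir)."""
    ctx: dict = {}
    for stage in STAGES:
        if stage in skip:
            continue
        _STAGE_FNS[stage](ctx, config)
    report = ctx.get("report", {})
    if config.outdir:
        _write_outputs(ctx, config)
    return report


# --------------------------------------------------------------------- stages

def _stage_simulate(ctx, cfg: RunConfig):
    ctx["study"] = simulate_all(cfg.sim)


def _stage_srf(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "srf")
    chip = study.chip
    by_label = {
        label: chip.peaks[f"SRF_{label}"]
        for label, _cond in (("resting1", None), ("resting2", None),
                             ("stim1", None), ("stim2", None),
                             ("LatB", None), ("U0126", None))
    }
    core = pc.call_srf_core(by_label, cfg.stringent_p, cfg.slop)
    ctx["srf_core"] = core
    ctx["srf_low_peaks"] = [p for peaks in by_label.values() for p in peaks
                            if p.pvalue >= cfg.stringent_p]

    signals = ind.quantify_sites(core, chip.srf_tracks, cfg.window_bp,
                                 cfg.pseudocount)
    fit = ind.select_threshold(signals, cfg.grid)
    labels, _ = ind.classify_sites(signals, fit.threshold)
    flags = ind.sensitivity_flags(signals, cfg.latB_cut, cfg.u0126_cut)
    ctx["threshold_fit"] = fit
    ctx["srf_core_signals"] = signals
    ctx["srf_core_labels"] = labels
    ctx["srf_core_flags"] = flags
    qualifying = [
        s for s in core
        if labels[s.id] == "inducible" and flags.at[s.id, "latB_sensitive"]]
    ctx["srf_qualifying"] = qualifying


def _stage_mrtf(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "mrtf")
    chip = study.chip
    qualifying = _need(ctx, "srf_qualifying", "srf", "mrtf")
    peaksA = [p for c in ("resting", "stimulated", "LatB", "U0126")
              for p in chip.peaks[f"MRTF-A_{c}"]]
    peaksB = [p for c in ("resting", "stimulated", "LatB", "U0126")
              for p in chip.peaks[f"MRTF-B_{c}"]]
    mrtf_sites = pc.call_mrtf(peaksA, peaksB, qualifying,
                              cfg.stringent_p, cfg.low_p, cfg.slop)
    ctx["mrtf_sites"] = mrtf_sites
    ctx["mrtf_stringent_peaks"] = [
        p for p in peaksA + peaksB if p.pvalue < cfg.stringent_p]

    # SRF rescue pass (needs stringent MRTF peaks)
    inducibility_fn, latB_fn = ind.make_ratio_fns(
        chip.srf_tracks, cfg.window_bp, cfg.pseudocount)
    rescued = pc.rescue_srf(
        ctx["srf_low_peaks"], ctx["srf_core"], ctx["mrtf_stringent_peaks"],
        inducibility_fn, latB_fn, cfg.low_p, cfg.rescue_inducibility,
        cfg.latB_cut, cfg.slop)
    ctx["srf_rescued"] = rescued
    ctx["srf_sites"] = list(ctx["srf_core"]) + rescued


def _stage_tcf(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "tcf")
    chip = study.chip
    peaks = [p for m in ("SAP-1", "Elk-1", "Net")
             for c in ("resting", "stimulated", "LatB", "U0126")
             for p in chip.peaks[f"{m}_{c}"]]
    ctx["tcf_sites"] = pc.call_tcf(peaks, cfg.stringent_p, cfg.slop)


def _stage_classify(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "classify")
    sites = _need(ctx, "srf_sites", "mrtf", "classify")
    signals = ind.quantify_sites(sites, study.chip.srf_tracks,
                                 cfg.window_bp, cfg.pseudocount)
    fit = ctx.get("threshold_fit") or ind.select_threshold(signals, cfg.grid)
    labels, summary = ind.classify_sites(signals, fit.threshold)
    flags = ind.sensitivity_flags(signals, cfg.latB_cut, cfg.u0126_cut)
    ctx["srf_signals"] = signals
    ctx["srf_labels"] = labels
    ctx["srf_class_summary"] = summary
    ctx["srf_flags"] = flags


def _stage_carg(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "carg")
    sites = _need(ctx, "srf_sites", "mrtf", "carg")
    labels = _need(ctx, "srf_labels", "classify", "carg")
    stim = study.chip.srf_tracks["stimulated"]
    scale = 1e6 / stim.library_size
    carg, heights = {}, {}
    for s in sites:
        carg[s.id] = ms.classify_carg(s, study.genome, cfg.carg_window_bp,
                                      max_mismatch=cfg.carg_budget).best
        arr = stim.data[s.chrom][s.interval.start:s.interval.end]
        heights[s.id] = float(arr.max()) * scale if len(arr) else 0.0
    ctx["carg_class"] = pd.Series(carg, name="carg")
    ctx["peak_height"] = pd.Series(heights, name="height")
    ctx["carg_stats"] = ms.match_class_statistics(
        ctx["carg_class"], ctx["peak_height"], site_class=labels,
        window_bp=cfg.carg_window_bp)


def _stage_cofactor(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "cofactor")
    srf_sites = _need(ctx, "srf_sites", "mrtf", "cofactor")
    mrtf_sites = _need(ctx, "mrtf_sites", "mrtf", "cofactor")
    tcf_sites = _need(ctx, "tcf_sites", "tcf", "cofactor")
    calls, orphans = cf.assign_cofactors(srf_sites, mrtf_sites, tcf_sites,
                                         cfg.slop)
    table = cf.score_calls(calls, study.chip.mrtf_tracks["stimulated"],
                           study.chip.tcf_tracks["resting"],
                           cfg.window_bp, cfg.dominance_fold)
    ctx["cofactor_calls"] = table
    ctx["mrtf_orphans"] = orphans
    ctx["mrtf_concordance"] = cf.mrtf_ab_concordance(
        mrtf_sites, study.chip.mrtfA_stim, study.chip.mrtfB_stim,
        cfg.window_bp)


def _stage_expression(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "expression")
    counts, meta = study.rna_counts, study.rna_meta
    norm = {}
    fits = {}
    for rc in ("all", "intronic"):
        cols = meta.index[meta["read_class"] == rc]
        fit = ex.fit_normalization(counts[cols], meta.loc[cols, "condition"],
                                   mode=cfg.norm_mode)
        fits[rc] = fit
        norm[rc] = fit.normalize(counts[cols])
    normalized = pd.concat(norm.values(), axis=1)
    contrasts = {}
    for rc in ("all", "intronic"):
        for key, test, ref in (("stim_vs_rest", "stimulated", "resting"),
                               ("latB_vs_stim", "LatB", "stimulated"),
                               ("u0126_vs_stim", "U0126", "stimulated"),
                               ("cd_vs_rest", "CD", "resting")):
            contrasts[f"{key}_{rc}"] = ex.run_contrast(
                normalized, meta, test, ref, rc)
    serum = ex.classify_serum_response(
        contrasts["stim_vs_rest_all"], contrasts["stim_vs_rest_intronic"],
        cfg.fdr_serum)
    flags = ex.classify_pathway(serum, contrasts, cfg.fdr_pathway)
    exon_kb = pd.Series(
        {g.id: sum(len(e) for e in g.exons) / 1000 for g in study.genes})
    active = ex.active_genes(normalized, meta, exon_kb,
                             cfg.active_floor_per_kb)
    ctx["norm_fits"] = fits
    ctx["normalized_counts"] = normalized
    ctx["contrasts"] = contrasts
    ctx["serum_class"] = serum
    ctx["pathway_flags"] = flags
    ctx["active_genes"] = active


def _stage_targets(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "targets")
    srf_sites = _need(ctx, "srf_sites", "mrtf", "targets")
    cof = _need(ctx, "cofactor_calls", "cofactor", "targets")
    serum = _need(ctx, "serum_class", "expression", "targets")
    flags = _need(ctx, "pathway_flags", "expression", "targets")
    active = _need(ctx, "active_genes", "expression", "targets")
    links = tg.link_sites_to_genes(srf_sites, study.genes,
                                   cfg.near_bp, cfg.promoter_bp)
    sets_ = tg.define_target_sets(links, serum, flags,
                                  cof["cofactor_class"])
    act = [g for g in study.genes if active.get(g.id, False)]
    inact = [g for g in study.genes if not active.get(g.id, False)]
    enrich = tg.distance_enrichment(srf_sites, act, inact,
                                    promoter_bp=cfg.promoter_bp)
    ctx["links"] = links
    ctx["target_sets"] = sets_
    ctx["distance_enrichment"] = enrich
    ctx["mrtf_tcf_overlap"] = tg.signature_overlap(
        sets_.mrtf_candidates, sets_.tcf_targets,
        set(serum.index))


def _stage_polii(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "polii")
    serum = _need(ctx, "serum_class", "expression", "polii")
    flags = _need(ctx, "pathway_flags", "expression", "polii")
    latB_sensitive = set(
        flags.index[(serum == "inducible") & flags["latB_impaired"]])
    genes = [g for g in study.genes if g.id in latB_sensitive]
    groups = pp.classify_groups(
        genes, study.polii_tracks[("8WG16", "stimulated")],
        study.polii_tracks[("8WG16", "LatB")], cfg.group_threshold)
    ctx["polii_groups"] = groups
    by_group = {grp: [g for g in genes
                      if groups.at[g.id, "group"] == grp]
                for grp in ("I", "II")}
    profiles = {}
    for grp, gs in by_group.items():
        usable = [g for g in gs if g.length >= 10_000]
        if usable:
            for ab in ("8WG16", "H14", "H5"):
                profiles[(grp, ab)] = pp.metaprofile_genes(
                    study.polii_tracks[(ab, "stimulated")], usable)
    ctx["polii_profiles"] = profiles


def _stage_h3(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "h3")
    sites = _need(ctx, "srf_sites", "mrtf", "h3")
    labels = _need(ctx, "srf_labels", "classify", "h3")
    table = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "summit": [s.summit_pos for s in sites],
        "class": [labels[s.id] for s in sites],
    }, index=[s.id for s in sites])
    ctx["h3"] = pp.h3_metaprofile(study.h3_tracks, table,
                                  cfg.h3_half_width, cfg.h3_bin_bp,
                                  cfg.h3_normalize_to)


# --------------------------------------------------------------------- report

def _stage_report(ctx, cfg: RunConfig):
    study = _need(ctx, "study", "simulate", "report")
    truth = study.truth
    report: dict = {"config_seed": cfg.sim.seed}

    # --- site recovery per family
    fam_truth = {
        "SRF": truth.sites[~truth.sites["orphan"]],
        "MRTF": truth.sites[truth.sites["cofactor"].isin(
            ["MRTF", "both", "MRTF-orphan"])],
        "TCF": truth.sites[truth.sites["cofactor"].isin(["TCF", "both"])],
    }
    fam_called = {
        "SRF": ctx["srf_sites"], "MRTF": ctx["mrtf_sites"],
        "TCF": ctx["tcf_sites"]}
    sites_rep = {}
    srf_assign = None
    for fam in fam_truth:
        assign, matched = _match_sites(fam_called[fam], fam_truth[fam],
                                       cfg.match_bp)
        if fam == "SRF":
            srf_assign = assign
        n_truth = len(fam_truth[fam])
        n_called = len(fam_called[fam])
        sites_rep[fam] = {
            "n_called": n_called,
            "n_truth": n_truth,
            "sensitivity": len(matched) / n_truth if n_truth else np.nan,
            "spurious_fraction": float((assign < 0).mean())
            if n_called else np.nan,
        }
    sites_rep["SRF"]["n_core"] = len(ctx["srf_core"])
    sites_rep["SRF"]["n_rescued"] = len(ctx["srf_rescued"])
    report["sites"] = sites_rep

    # --- threshold + class recovery (matched SRF sites only)
    fit = ctx["threshold_fit"]
    labels = ctx["srf_labels"]
    srf_truth = fam_truth["SRF"]
    ok = srf_assign >= 0
    called_ids = np.array([s.id for s in ctx["srf_sites"]])
    truth_cls = srf_truth.loc[srf_assign[ok], "ind_class"].to_numpy()
    called_cls = labels[called_ids[ok]].to_numpy()
    class_acc = float((truth_cls == called_cls).mean())
    flags = ctx["srf_flags"]
    ind_mrtf = ok & np.isin(
        srf_assign,
        srf_truth.index[(srf_truth["ind_class"] == "inducible")
                        & srf_truth["cofactor"].isin(["MRTF", "both"])])
    latB_recov = float(
        flags.loc[called_ids[ind_mrtf], "latB_sensitive"].mean())
    summary = ctx["srf_class_summary"]
    report["inducibility"] = {
        "threshold": fit.threshold,
        "slope_constitutive": fit.slope_constitutive,
        "class_accuracy": class_acc,
        "latB_flag_sensitivity": latB_recov,
        "n_constitutive": int(summary.at["constitutive", "n"]),
        "n_inducible": int(summary.at["inducible", "n"]),
        "mean_inducibility_constitutive":
            float(summary.at["constitutive", "mean_inducibility"]),
        "mean_inducibility_inducible":
            float(summary.at["inducible", "mean_inducibility"]),
    }

    # --- CArG recovery
    carg = ctx["carg_class"]
    cls_map = {0: "perfect", 1: "1mm", 2: "2mm", -1: "none"}
    truth_carg = srf_truth.loc[srf_assign[ok], "carg_mm"].map(
        cls_map).to_numpy()
    called_carg = carg[called_ids[ok]].to_numpy()
    report["carg"] = {
        "recovery": float((truth_carg == called_carg).mean()),
        "class_counts": carg.value_counts().to_dict(),
    }

    # --- cofactor accuracy (non-orphan truth classes)
    cof = ctx["cofactor_calls"]["cofactor_class"]
    truth_cof = srf_truth.loc[srf_assign[ok], "cofactor"].to_numpy()
    called_cof = cof.reindex(called_ids[ok]).to_numpy()
    keep = truth_cof != "MRTF-orphan"
    report["cofactor"] = {
        "accuracy": float((truth_cof[keep] == called_cof[keep]).mean()),
        "n_orphan_mrtf": len(ctx["mrtf_orphans"]),
        "class_counts": cof.value_counts().to_dict(),
    }

    # --- normalization recovery
    fit_all = ctx["norm_fits"]["all"]
    s = fit_all.scale_factors
    meta = study.rna_meta
    planted = truth.scale_factors
    errs = []
    for cond in planted:
        cols = meta.index[(meta["read_class"] == "all")
                          & (meta["condition"] == cond)]
        est = float(s.reindex(cols).mean())
        errs.append(abs(est - planted[cond] / planted["resting"])
                    / (planted[cond] / planted["resting"]))
    report["normalization"] = {
        "n_stable_genes": int(len(fit_all.stable_genes)),
        "max_scale_factor_rel_error": float(max(errs)),
    }

    # --- DE recovery
    serum = ctx["serum_class"]
    truth_resp = truth.genes.set_index("gene_id")["response"]
    called_ind = serum == "inducible"
    truth_ind = truth_resp.reindex(serum.index) == "inducible"
    tp = int((called_ind & truth_ind).sum())
    report["expression"] = {
        "n_inducible_called": int(called_ind.sum()),
        "de_sensitivity": tp / int(truth_ind.sum()),
        "de_fdr": 1 - tp / int(called_ind.sum()) if called_ind.any()
        else np.nan,
    }
    # pathway label recovery among correctly-detected inducible genes
    flags_df = ctx["pathway_flags"]
    pred = pd.Series("none", index=serum.index)
    pred[flags_df["u0126_impaired"]] = "TCF"
    pred[flags_df["latB_impaired"] | flags_df["cd_inducible"]] = "MRTF"
    truth_path = truth.genes.set_index("gene_id")["pathway"]
    both = serum.index[called_ind & truth_ind]
    report["expression"]["pathway_accuracy"] = float(
        (pred[both] == truth_path.reindex(both)).mean())

    # --- target sets
    sets_ = ctx["target_sets"]
    report["targets"] = sets_.sizes()
    g = truth.genes.set_index("gene_id")
    hosted = set(truth.sites.loc[~truth.sites["orphan"], "host_gene"]) - {""}
    truth_srf = set(g.index[(g["response"] == "inducible")]) & hosted
    mrtf_hosted = set(truth.sites.loc[
        truth.sites["cofactor"].isin(["MRTF", "both"]), "host_gene"]) - {""}
    truth_mrtf = truth_srf & (
        mrtf_hosted | set(g.index[g["latB_impaired"] | g["cd_inducible"]]))
    rec = sets_.srf_targets & truth_srf
    report["targets"]["srf_target_recovery"] = (
        len(rec) / len(truth_srf) if truth_srf else np.nan)
    report["targets"]["srf_target_precision"] = (
        len(rec) / len(sets_.srf_targets) if sets_.srf_targets else np.nan)
    report["targets"]["mrtf_candidate_recovery"] = (
        len(sets_.mrtf_candidates & truth_mrtf) / len(truth_mrtf)
        if truth_mrtf else np.nan)
    report["targets"]["inclusion_chain_ok"] = bool(
        sets_.mrtf_stringent <= sets_.mrtf_candidates <= sets_.srf_targets)
    report["targets"]["distance_rank_sum_p"] = \
        ctx["distance_enrichment"]["rank_sum_p"]
    report["targets"]["distance_fisher_p"] = \
        ctx["distance_enrichment"]["fisher_p"]

    # --- Pol II groups
    groups = ctx["polii_groups"]
    truth_grp = g["polii_group"]
    common = groups.index.intersection(truth_grp.index[truth_grp != ""])
    acc = float((groups.loc[common, "group"]
                 == truth_grp.loc[common]).mean()) if len(common) else np.nan
    report["polii"] = {
        "n_group_I": int((groups["group"] == "I").sum()),
        "n_group_II": int((groups["group"] == "II").sum()),
        "group_accuracy": acc,
        "n_classified": int(len(groups)),
    }

    # --- H3
    tests = ctx["h3"]["tests"]
    dips = ctx["h3"]["dips"]
    report["h3"] = {
        "p_inducible_stim_vs_rest":
            tests.get(("inducible", "stimulated_vs_resting"), np.nan),
        "p_inducible_latB_vs_rest":
            tests.get(("inducible", "LatB_vs_resting"), np.nan),
        "p_constitutive_stim_vs_rest":
            tests.get(("constitutive", "stimulated_vs_resting"), np.nan),
        "mean_dip_inducible_resting":
            float(np.nanmean(dips[("inducible", "resting")])),
        "mean_dip_inducible_stimulated":
            float(np.nanmean(dips[("inducible", "stimulated")])),
    }
    ctx["report"] = report


_STAGE_FNS: dict[str, Callable] = {
    "simulate": _stage_simulate,
    "srf": _stage_srf,
    "mrtf": _stage_mrtf,
    "tcf": _stage_tcf,
    "classify": _stage_classify,
    "carg": _stage_carg,
    "cofactor": _stage_cofactor,
    "expression": _stage_expression,
    "targets": _stage_targets,
    "polii": _stage_polii,
    "h3": _stage_h3,
    "report": _stage_report,
}


# --------------------------------------------------------------------- output

def _sites_frame(sites) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "start": [s.interval.start for s in sites],
        "end": [s.interval.end for s in sites],
        "site_id": [s.id for s in sites],
        "summit": [s.summit_pos for s in sites],
        "rescued": [s.rescued for s in sites],
        "label": [s.label or "" for s in sites],
        "n_evidence": [len(s.evidence) for s in sites],
    })


def _write_outputs(ctx, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = ctx["study"]
    study.truth.write(out)
    for fam, key in (("srf", "srf_sites"), ("mrtf", "mrtf_sites"),
                     ("tcf", "tcf_sites")):
        if key in ctx:
            _sites_frame(ctx[key]).to_csv(
                out / f"{fam}_sites.tsv", sep="\t", index=False)
    if "srf_signals" in ctx:
        df = ctx["srf_signals"].copy()
        df["class"] = ctx["srf_labels"]
        df = df.join(ctx["srf_flags"])
        df.to_csv(out / "srf_site_signals.tsv", sep="\t")
    if "cofactor_calls" in ctx:
        ctx["cofactor_calls"].to_csv(out / "cofactor_calls.tsv", sep="\t")
    if "serum_class" in ctx:
        resp = pd.DataFrame({"serum_class": ctx["serum_class"]})
        resp = resp.join(ctx["pathway_flags"])
        resp.to_csv(out / "gene_response.tsv", sep="\t")
    if "links" in ctx:
        ctx["links"].to_csv(out / "site_gene_links.tsv", sep="\t")
    if "polii_groups" in ctx:
        ctx["polii_groups"].to_csv(out / "polii_groups.tsv", sep="\t")
    if "report" in ctx:
        with open(out / "report.json", "w") as fh:
            json.dump(ctx["report"], fh, indent=2, default=float)
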