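"""RNA-seq normalization, NB differential testing, and response classes.

Normalization follows a stable-gene procedure: expression in unstimulated
cells is fitted to a Gaussian on the log2 scale, and the stable set
comprises genes whose log2 change in every condition (relative to the
per-sample median change, which absorbs the unknown scale factor) stays
within one fitted SD.  The mean count of the stable set then defines one
scale factor per sample, applied to all counts.

Differential expression uses an internal negative-binomial exact test:
the two summed counts are compared conditional on their total, with a
pooled method-of-moments dispersion shared across genes (the model that
count-based DE tools assume).  As dispersion approaches zero the test
reduces to the exact binomial test.  Multiple testing is controlled by
Benjamini-Hochberg.

A gene is serum-inducible when its total ("all reads") and/or intronic
read counts rise significantly after stimulation; pathway dependence is
flagged when induction is impaired by LatB (Rho-actin-MRTF) or U0126
(ERK-TCF) or reproduced by the MRTF activator CD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizationFit:
    """Stable gene set, its Gaussian, and per-sample scale factors."""

    stable_genes: pd.Index
    mu: float
    sigma: float
    scale_factors: pd.Series  # per sample, reference sample = 1
    mode: str

    def normalize(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts / self.scale_factors.reindex(counts.columns)


def fit_normalization(
    counts: pd.DataFrame,
    conditions: Mapping[str, str] | pd.Series,
    mode: str = "levels",
    reference: str | None = None,
    min_stable: int = 100,
    min_count: float = 5.0,
) -> NormalizationFit:
    """Stable-gene scale factors from a genes x samples count matrix.

    ``conditions`` maps sample name -> condition; the resting condition
    must be present.  ``mode='levels'`` takes the SD of the stability band
    from a Gaussian fitted to resting log2 expression; ``mode='changes'``
    fits it to the (median-centered) log2 changes themselves.  Genes with
    zero counts everywhere are excluded.  The per-sample change is
    median-centered before the +/- 1 SD band is applied, so the selection
    is invariant to each sample's unknown scale factor.

    Genes whose mean resting count falls below ``min_count`` are excluded
    from both the Gaussian fit and the stable set: silent genes carry no
    information about sequencing scale and their log-counts form a
    separate mode that would corrupt the fitted SD.
    """
    conditions = pd.Series(dict(conditions) if not isinstance(
        conditions, pd.Series) else conditions)
    rest_samples = conditions.index[conditions == "resting"]
    if len(rest_samples) == 0:
        raise ValueError("no resting samples present")
    counts = counts.loc[counts.sum(axis=1) > 0]
    counts = counts.loc[counts[rest_samples].mean(axis=1) >= min_count]
    L = np.log2(counts + 1.0)
    rest_level = L[rest_samples].mean(axis=1)

    lfc = L.sub(rest_level, axis=0)
    centered = lfc.sub(lfc.median(axis=0), axis=1)
    if mode == "levels":
        mu, sigma = float(rest_level.mean()), float(rest_level.std(ddof=1))
    elif mode == "changes":
        flat = centered.to_numpy().ravel()
        mu, sigma = 0.0, float(np.std(flat, ddof=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stable_mask = (centered.abs() <= sigma).all(axis=1)
    stable = counts.index[stable_mask]
    if len(stable) < min_stable:
        raise ValueError(
            f"stable gene set too small ({len(stable)} < {min_stable})")

    reference = reference or rest_samples[0]
    ref_mean = counts.loc[stable, reference].mean()
    s = counts.loc[stable].mean(axis=0) / ref_mean
    return NormalizationFit(stable, mu, sigma, s, mode)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts_A: np.ndarray, counts_B: np.ndarray
) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    For NB counts, Var = mu + phi mu^2; summing (var - mean) and mean^2
    over genes and conditions (those with >= 2 replicates) gives a single
    pooled phi.  Clipped to a small positive floor.
    """
    num = 0.0
    den = 0.0
    for arr in (np.atleast_2d(counts_A), np.atleast_2d(counts_B)):
        if arr.shape[1] < 2:
            continue
        m = arr.mean(axis=1)
        v = arr.var(axis=1, ddof=1)
        # pool over a central expression band: the m^2 weights would
        # otherwise be dominated by a handful of very large genes, making
        # the pooled estimate noisy enough to distort test calibration
        pos = m > 0
        if pos.sum() >= 50:
            lo, hi = np.quantile(m[pos], [0.2, 0.9])
            keep = pos & (m >= lo) & (m <= hi)
        else:
            keep = pos
        num += float((v[keep] - m[keep]).sum())
        # E[m_hat^2] = m^2 + sigma^2/n_reps: subtract the plug-in v/n to
        # keep the pooled ratio unbiased (else phi is low and tests liberal)
        nrep = arr.shape[1]
        den += float(np.clip(m[keep] ** 2 - v[keep] / nrep, 0, None).sum())
    if den == 0:
        return 1e-8
    return max(num / den, 1e-8)


def _nb_exact_p(kA: int, kB: int, nA: int, nB: int, phi: float) -> float:
    """Two-sided conditional NB exact test on summed replicate counts.

    Under the null both sides share a per-replicate mean; conditioning on
    s = kA + kB, the probability of each split x is proportional to
    NB(x; nA reps) * NB(s - x; nB reps).  The two-sided p sums the
    probabilities of all splits no more likely than the observed one.
    """
    s = kA + kB
    if s == 0:
        return 1.0
    lam = s / (nA + nB)
    rA, rB = nA / phi, nB / phi
    muA, muB = nA * lam, nB * lam
    pA = rA / (rA + muA)
    pB = rB / (rB + muB)
    # enumerate a window wide enough that the truncated tails are negligible
    sd = np.sqrt(muA + phi / nA * muA ** 2)
    lo = max(0, int(muA - 30 * sd - 5))
    hi = min(s, int(muA + 30 * sd + 5))
    lo, hi = min(lo, kA), max(hi, kA)
    x = np.arange(lo, hi + 1)
    logp = (stats.nbinom.logpmf(x, rA, pA)
            + stats.nbinom.logpmf(s - x, rB, pB))
    logp -= logp.max()
    probs = np.exp(logp)
    total = probs.sum()
    obs = probs[kA - lo]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum() / total, 1.0))


def nb_test(
    counts_A: np.ndarray | pd.DataFrame,
    counts_B: np.ndarray | pd.DataFrame,
    dispersion: float | None = None,
) -> np.ndarray:
    """Per-gene two-sided NB exact test p-values.

    ``counts_A``/``counts_B`` are genes x replicates (a 1-D vector is one
    replicate).  When ``dispersion`` is None it is estimated by the pooled
    method of moments; with a single replicate per side, supply a
    dispersion or accept the floor value (Poisson-like).
    """
    A = np.atleast_2d(np.asarray(counts_A, dtype=float))
    B = np.atleast_2d(np.asarray(counts_B, dtype=float))
    if A.ndim == 2 and A.shape[0] == 1 and np.asarray(counts_A).ndim == 1:
        A = A.T
    if B.ndim == 2 and B.shape[0] == 1 and np.asarray(counts_B).ndim == 1:
        B = B.T
    if A.shape[0] != B.shape[0]:
        raise ValueError("count matrices must have the same gene dimension")
    phi = estimate_dispersion(A, B) if dispersion is None else max(
        dispersion, 1e-8)
    kA = np.rint(A.sum(axis=1)).astype(np.int64)
    kB = np.rint(B.sum(axis=1)).astype(np.int64)
    nA, nB = A.shape[1], B.shape[1]
    return np.array([_nb_exact_p(int(a), int(b), nA, nB, phi)
                     for a, b in zip(kA, kB)])


def bh_fdr(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


# ---------------------------------------------------------------------------
# contrasts and classification
# ---------------------------------------------------------------------------

def run_contrast(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    cond_test: str,
    cond_ref: str,
    read_class: str,
    dispersion: float | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2FC, p and BH q for one condition contrast in one read class.

    ``norm_counts`` must already be scale-normalized; meta needs columns
    condition and read_class indexed by sample.
    """
    sel = meta["read_class"] == read_class
    test_cols = meta.index[sel & (meta["condition"] == cond_test)]
    ref_cols = meta.index[sel & (meta["condition"] == cond_ref)]
    if len(test_cols) == 0 or len(ref_cols) == 0:
        raise ValueError(f"missing samples for {cond_test} vs {cond_ref} "
                         f"({read_class})")
    A = norm_counts[test_cols]
    B = norm_counts[ref_cols]
    p = nb_test(A.to_numpy(), B.to_numpy(), dispersion=dispersion)
    lfc = np.log2((A.mean(axis=1) + pseudocount)
                  / (B.mean(axis=1) + pseudocount))
    return pd.DataFrame({
        "lfc": lfc, "p": p, "q": bh_fdr(p)}, index=norm_counts.index)


def classify_serum_response(
    res_all: pd.DataFrame,
    res_intronic: pd.DataFrame,
    fdr_serum: float = 0.2,
) -> pd.Series:
    """inducible / repressed / unchanged from the two stimulated-vs-resting
    contrasts, combined by the and/or rule (significant in either read
    class counts).  A gene significant in opposite directions is left
    unchanged with a warning."""
    up = ((res_all["q"] < fdr_serum) & (res_all["lfc"] > 0)) | \
         ((res_intronic["q"] < fdr_serum) & (res_intronic["lfc"] > 0))
    down = ((res_all["q"] < fdr_serum) & (res_all["lfc"] < 0)) | \
           ((res_intronic["q"] < fdr_serum) & (res_intronic["lfc"] < 0))
    conflict = up & down
    if conflict.any():
        warnings.warn(f"{int(conflict.sum())} gene(s) significant in "
                      "opposite directions; left unchanged")
    out = pd.Series("unchanged", index=res_all.index, name="serum_class")
    out[up & ~conflict] = "inducible"
    out[down & ~conflict] = "repressed"
    return out


def classify_pathway(
    serum_class: pd.Series,
    contrasts: Mapping[str, pd.DataFrame],
    fdr_pathway: float = 0.08,
) -> pd.DataFrame:
    """Pathway-dependence flags over the serum-responsive genes.

    ``contrasts`` must hold, per read class suffix ("_all"/"_intronic"
    optional), DataFrames for "latB_vs_stim", "u0126_vs_stim" and
    "cd_vs_rest".  For an inducible gene, LatB-impaired means LatB
    significantly *below* stimulated; for a repressed gene the directions
    flip (inhibition of repression raises the count).  CD-inducible means
    CD moves the gene away from resting in the serum direction.
    q-values are recomputed within the responsive gene set, where the
    question is actually asked.
    """
    responsive = serum_class.index[serum_class != "unchanged"]
    sign = pd.Series(np.where(serum_class == "repressed", -1.0, 1.0),
                     index=serum_class.index)
    flags = pd.DataFrame(
        False, index=serum_class.index,
        columns=["latB_impaired", "u0126_impaired", "cd_inducible"])
    key_map = {"latB_vs_stim": ("latB_impaired", -1),
               "u0126_vs_stim": ("u0126_impaired", -1),
               "cd_vs_rest": ("cd_inducible", +1)}
    for key, (col, direction) in key_map.items():
        hits = pd.Series(False, index=responsive)
        for suffix in ("_all", "_intronic", ""):
            full = key + suffix
            if full not in contrasts:
                continue
            res = contrasts[full].loc[responsive]
            q = bh_fdr(res["p"].to_numpy())
            effect = res["lfc"] * sign.loc[responsive]
            hits |= pd.Series(
                (q < fdr_pathway) & (direction * effect > 0).to_numpy(),
                index=responsive)
        flags.loc[responsive, col] = hits
    flags["srf_linked"] = flags.any(axis=1) & (serum_class != "unchanged")
    return flags


def active_genes(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    exon_kb: pd.Series,
    floor_per_kb: float = 1.0,
) -> pd.Series:
    """Detectably transcribed genes: mean normalized all-read count per kb
    of exon above a floor."""
    all_cols = meta.index[meta["read_class"] == "all"]
    mean_counts = norm_counts[all_cols].mean(axis=1)
    per_kb = mean_counts / exon_kb.reindex(mean_counts.index)
    return per_kb >= floor_per_kb
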