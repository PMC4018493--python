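"""IUPAC consensus scanning with mismatch budgets; CArG-box classification.

The SRF binding consensus is the CArG box CC(A/T)6GG, written CCWWWWWWGG
in IUPAC code.  Sites are classified by the best match (perfect, single
or double mismatch, or none) found within a window centered on the peak
summit, and match classes are related to peak height, binding
inducibility and cofactor association.

Mismatch counting treats IUPAC degeneracy as satisfied/violated per
position (W is matched by A or T, nothing in between); an N in the
scanned sequence matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import fetch_seq

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: The SRF-binding CArG-box consensus.
CARG_CONSENSUS = "CCWWWWWWGG"

#: Known SRF-associated motifs used for cofactor-class motif frequencies.
KNOWN_MOTIFS: dict[str, str] = {
    "AP-1": "TGASTCA",
    "Ets": "GGAW",
    "SP1": "GGGCGG",
    "NFY": "CCAAT",
    "TEAD": "GGAATG",
    "CRE": "TGACGTCA",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifMatch:
    consensus: str
    position: int  # 0-based offset of the match start within the scanned sequence
    strand: str
    mismatches: int


@dataclass
class CargClass:
    """Best CArG match class at a site plus per-class match counts."""

    best: str  # one of {"perfect", "1mm", "2mm", "none"}
    n_matches: dict[str, int] = field(default_factory=dict)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from exc


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, b in enumerate(seq):
        code = _BASE_CODE.get(b)
        if code is None:
            raise ValueError(f"invalid sequence base {b!r} at position {i}")
        out[i] = code
    return out


def _allowed_table(consensus: str) -> np.ndarray:
    """(motif_len, 5) boolean table; row j marks bases matching position j."""
    table = np.zeros((len(consensus), 5), dtype=bool)
    for j, c in enumerate(consensus.upper()):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in consensus")
        for b in IUPAC[c]:
            table[j, _BASE_CODE[b]] = True
        # N in the scanned sequence matches nothing: column 4 stays False.
    return table


def _mismatch_counts(codes: np.ndarray, consensus: str) -> np.ndarray:
    """Per-offset Hamming distance (IUPAC-aware) of the consensus to the sequence."""
    L = len(consensus)
    if codes.size < L:
        return np.zeros(0, dtype=np.int32)
    table = _allowed_table(consensus)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    ok = table[np.arange(L)[None, :], windows]
    return (L - ok.sum(axis=1)).astype(np.int32)


def scan_iupac(
    sequence: str,
    consensus: str,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[MotifMatch]:
    """All matches of an IUPAC consensus with at most ``max_mismatch`` mismatches.

    A minus-strand match at position i means the reverse complement of
    ``sequence[i:i+L]`` matches the consensus.  When both strands match the
    same interval (as happens at every position for reverse-complement-
    closed consensi such as the CArG box), the duplicate is collapsed to a
    single record keeping the smaller mismatch count (plus strand on ties).
    """
    codes = _encode(sequence)
    fwd = _mismatch_counts(codes, consensus)
    rc = reverse_complement(consensus)
    matches: dict[int, MotifMatch] = {}
    for pos in np.flatnonzero(fwd <= max_mismatch):
        matches[int(pos)] = MotifMatch(consensus, int(pos), "+", int(fwd[pos]))
    if both_strands:
        rev = _mismatch_counts(codes, rc)
        for pos in np.flatnonzero(rev <= max_mismatch):
            pos = int(pos)
            m = int(rev[pos])
            prev = matches.get(pos)
            if prev is None:
                matches[pos] = MotifMatch(consensus, pos, "-", m)
            elif m < prev.mismatches:
                matches[pos] = MotifMatch(consensus, pos, "-", m)
    return [matches[p] for p in sorted(matches)]


_CLASS_NAMES = {0: "perfect", 1: "1mm", 2: "2mm"}


def classify_carg(
    site,
    genome,
    window_bp: int = 200,
    consensus: str = CARG_CONSENSUS,
    max_mismatch: int = 2,
) -> CargClass:
    """Best CArG-consensus match within ``window_bp``/2 of the site summit.

    ``site`` needs ``chrom``/``summit_pos`` attributes (a Peak or Site) or a
    ``(chrom, summit)`` tuple; ``genome`` is a dict of sequences or a
    pyfaidx Fasta.
    """
    if hasattr(site, "summit_pos"):
        chrom, summit = site.chrom, site.summit_pos
    elif hasattr(site, "summit") and hasattr(site, "chrom"):
        chrom, summit = site.chrom, site.summit
    else:
        chrom, summit = site
    half = window_bp // 2
    seq = fetch_seq(genome, chrom, summit - half, summit + half)
    hits = scan_iupac(seq, consensus, max_mismatch=max_mismatch)
    counts = {name: 0 for name in ("perfect", "1mm", "2mm")}
    for h in hits:
        if h.mismatches in _CLASS_NAMES:
            counts[_CLASS_NAMES[h.mismatches]] += 1
    best = "none"
    for m in range(max_mismatch + 1):
        if counts.get(_CLASS_NAMES.get(m, ""), 0) > 0:
            best = _CLASS_NAMES[m]
            break
    return CargClass(best, counts)


def expected_match_frequency(
    consensus: str, window_len: int, max_mismatch: int = 0
) -> float:
    """Expected number of matches in a random i.i.d. ACGT sequence.

    Computed exactly per offset from the per-position match probabilities
    (|allowed bases|/4), with the mismatch-count distribution obtained by
    convolving the per-position Bernoulli misses.  For reverse-complement-
    closed consensi a plus- and minus-strand match at an offset are the
    same event, so no strand doubling applies; otherwise the two strands
    are counted separately (overlap of the two events is neglected).
    """
    probs = [len(IUPAC[c]) / 4.0 for c in consensus.upper()]
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [p, 1.0 - p])
    p_match = float(dist[: max_mismatch + 1].sum())
    n_offsets = max(window_len - len(consensus) + 1, 0)
    strands = 1 if reverse_complement(consensus) == consensus.upper() else 2
    return strands * n_offsets * p_match


def sampled_match_frequency(
    consensus: str,
    window_len: int,
    max_mismatch: int = 0,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of the chance match count in random sequences."""
    rng = rng or np.random.default_rng(0)
    total = 0
    bases = np.array(list("ACGT"))
    for _ in range(n_draws):
        seq = "".join(bases[rng.integers(0, 4, size=window_len)])
        total += len(scan_iupac(seq, consensus, max_mismatch=max_mismatch))
    return total / n_draws


def match_class_statistics(
    carg: pd.Series,
    heights: pd.Series,
    site_class: pd.Series | None = None,
    cofactor: pd.Series | None = None,
    window_bp: int = 200,
    expected_mode: str = "analytic",
    rng: np.random.Generator | None = None,
) -> dict:
    """Summary statistics relating CArG match class to peak properties.

    Parameters are aligned pandas Series indexed by site id: ``carg`` holds
    the best-match class, ``heights`` the peak height, and optionally
    ``site_class`` (constitutive/inducible) and ``cofactor``.  Returns a
    dict with a per-class summary table, pairwise two-sided rank-sum
    p-values on heights, cross-tabulations, and the expected-by-chance
    match frequency per class in random sequences of the scanned window.
    """
    order = ["perfect", "1mm", "2mm", "none"]
    classes = [c for c in order if (carg == c).any()]
    summary = pd.DataFrame({
        "n": [(carg == c).sum() for c in classes],
        "median_height": [float(heights[carg == c].median()) for c in classes],
    }, index=classes)

    pvals = pd.DataFrame(np.nan, index=classes, columns=classes)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            ha, hb = heights[carg == a], heights[carg == b]
            if len(ha) and len(hb):
                p = stats.mannwhitneyu(ha, hb, alternative="two-sided").pvalue
                pvals.loc[a, b] = pvals.loc[b, a] = p

    out = {"summary": summary, "rank_sum_p": pvals}
    if site_class is not None:
        out["by_inducibility"] = pd.crosstab(carg, site_class)
    if cofactor is not None:
        out["by_cofactor"] = pd.crosstab(carg, cofactor)

    expected = {}
    for budget, name in _CLASS_NAMES.items():
        if expected_mode == "analytic":
            cum = expected_match_frequency(CARG_CONSENSUS, window_bp, budget)
        else:
            cum = sampled_match_frequency(CARG_CONSENSUS, window_bp, budget,
                                          rng=rng)
        expected[name] = cum
    # convert cumulative (<= m mismatches) to per-class expectations
    out["expected_by_chance"] = {
        "perfect": expected["perfect"],
        "1mm": expected["1mm"] - expected["perfect"],
        "2mm": expected["2mm"] - expected["1mm"],
    }
    return out
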