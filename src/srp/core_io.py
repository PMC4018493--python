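"""Genomic primitives and readers/writers for the standard text formats.

All coordinates are 0-based, half-open (BED convention) throughout the
package.  GTF input (1-based, inclusive) is converted on read.

Formats handled here: ENCODE narrowPeak (BED6+4) and plain BED6 for peak
calls, GTF / BED12 for gene models, FASTA for genome sequence (via
:mod:`pyfaidx` when reading from disk), bedGraph for per-base signal
tracks, and plain TSV for count tables (via :mod:`pandas`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}

#: Antibodies appearing in the ChIP experiment design.
ANTIBODIES = {
    "SRF", "MRTF-A", "MRTF-B", "SAP-1", "Elk-1", "Net",
    "PolII-8WG16", "PolII-H14", "PolII-H5", "H3",
}

#: Cell-culture conditions.
CONDITIONS = {"resting", "stimulated", "LatB", "U0126", "CD"}


class FormatError(ValueError):
    """Raised on malformed input records; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2

    def overlaps(self, other: "GenomicInterval", slop: int = 0) -> bool:
        """True if the two intervals, each extended by ``slop``, share >=1 bp."""
        return (
            self.chrom == other.chrom
            and self.start - slop < other.end + slop
            and other.start - slop < self.end + slop
        )


@dataclass
class Peak:
    """A called ChIP enrichment interval with summit and provenance."""

    interval: GenomicInterval
    summit: int  # bp offset from interval.start
    score: float = 0.0
    pvalue: float = 1.0
    sample: str | None = None
    antibody: str | None = None
    condition: str | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value must be in (0, 1], got {self.pvalue}")

    @property
    def summit_pos(self) -> int:
        """Absolute genomic coordinate of the summit."""
        return self.interval.start + self.summit

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class GeneModel:
    """A gene with strand-aware TSS / polyadenylation site and exon structure."""

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.id} has zero exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.id} has overlapping exons")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end

    @property
    def pA(self) -> int:
        return self.interval.end if self.strand != "-" else self.interval.start

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start,
                                           self.interval.strand))
        return out

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class SignalTrack:
    """Per-chromosome read density at 1-bp resolution.

    ``library_size`` defaults to the sum of the stored values; tracks
    restricted to windows of the genome may carry a larger library size.
    """

    data: dict[str, np.ndarray]
    library_size: float | None = None

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            if np.any(arr < 0):
                raise ValueError(f"negative signal values on {chrom}")
        if self.library_size is None:
            self.library_size = float(sum(a.sum() for a in self.data.values()))
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def window_sum(self, chrom: str, start: int, end: int) -> tuple[float, bool]:
        """Sum of raw per-bp counts in [start, end), clipped at chromosome edges.

        Returns ``(sum, clipped)``; raises if the window lies entirely
        off-chromosome.
        """
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} not in track")
        n = len(self.data[chrom])
        if end <= 0 or start >= n:
            raise ValueError(
                f"window {chrom}:{start}-{end} entirely off chromosome (length {n})"
            )
        s, e = max(start, 0), min(end, n)
        return float(self.data[chrom][s:e].sum()), (s != start or e != end)


def coincident(a: Peak, b: Peak, mode: str = "overlap", slop: int = 0) -> bool:
    """Do two peaks mark the same locus?

    ``mode='overlap'``: intervals extended by ``slop`` share >=1 bp.
    ``mode='summit_within'``: summit distance <= ``slop``.
    Symmetric in its arguments, and reflexive for slop >= 0.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    if mode == "overlap":
        return a.interval.overlaps(b.interval, slop=slop)
    if mode == "summit_within":
        return a.chrom == b.chrom and abs(a.summit_pos - b.summit_pos) <= slop
    raise ValueError(f"unknown mode {mode!r}")


def window_count(
    track: SignalTrack,
    interval: GenomicInterval,
    normalize_to: float = 1e6,
) -> float:
    """Library-size-normalized read count in an interval.

    Edge windows are clipped, not dropped.  Raises when the interval lies
    entirely off the chromosome.
    """
    raw, _clipped = track.window_sum(interval.chrom, interval.start, interval.end)
    return raw * (normalize_to / track.library_size)


# ---------------------------------------------------------------------------
# narrowPeak / BED6
# ---------------------------------------------------------------------------

def read_narrowpeak(
    path: str | Path,
    sample: str | None = None,
    antibody: str | None = None,
    condition: str | None = None,
) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED6 file.

    narrowPeak column 8 is -log10(p); column 10 is the summit offset
    (-1 means unknown -> interval midpoint).  For BED6 input there is no
    p-value column; by convention the BED score is treated as a -log10(p)
    surrogate (pvalue = 10**(-score)) and the summit is the midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if len(fields) == 6:
                    chrom, start, end, name, score, strand = fields
                    start, end = int(start), int(end)
                    iv = GenomicInterval(chrom, start, end, strand)
                    summit = (end - start) // 2
                    pvalue = 10.0 ** (-float(score))
                elif len(fields) == 10:
                    (chrom, start, end, name, score, strand,
                     _signal, log10p, _log10q, summit) = fields
                    start, end = int(start), int(end)
                    iv = GenomicInterval(chrom, start, end, strand)
                    summit = int(summit)
                    if summit == -1:
                        summit = (end - start) // 2
                    lp = float(log10p)
                    pvalue = 1.0 if lp < 0 else 10.0 ** (-lp)
                else:
                    raise ValueError(
                        f"expected 6 or 10 columns, got {len(fields)}"
                    )
                peaks.append(Peak(iv, summit, float(score), pvalue,
                                  sample, antibody, condition, name))
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    peaks.sort(key=lambda p: (p.chrom, p.interval.start, p.interval.end))
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            log10p = -math.log10(p.pvalue) if p.pvalue > 0 else 999.0
            fh.write(
                "\t".join([
                    p.chrom, str(p.interval.start), str(p.interval.end),
                    p.name, f"{p.score:g}", p.interval.strand,
                    "0", f"{log10p:.6g}", "-1", str(p.summit),
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GTF / BED12)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (by extension .gtf/.gff) or BED12.

    GTF exon features are grouped by ``gene_id``; 1-based inclusive
    coordinates are converted to 0-based half-open.  A gene with zero
    exons is an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf(path)
    return _read_bed12(path)


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}, line {lineno}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}, line {lineno}: exon without gene_id")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if gid not in exons:
                order.append(gid)
            exons.setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        ivs = sorted(exons[gid], key=lambda e: e.start)
        span = GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end,
                               ivs[0].strand)
        genes.append(GeneModel(gid, span, ivs))
    if not genes:
        raise FormatError(f"{path}: no exon records found")
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}, line {lineno}: expected 12 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            start = int(start)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if not (len(sizes) == len(starts) == n_blocks) or n_blocks == 0:
                raise FormatError(f"{path}, line {lineno}: bad block definition")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
            genes.append(GeneModel(
                name, GenomicInterval(chrom, start, int(end), strand), exons))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "srp") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.id}"; transcript_id "{g.id}.t1";'
            fh.write("\t".join([
                g.interval.chrom, source, "gene",
                str(g.interval.start + 1), str(g.interval.end),
                ".", g.strand, ".", attr]) + "\n")
            for ex in g.exons:
                fh.write("\t".join([
                    ex.chrom, source, "exon",
                    str(ex.start + 1), str(ex.end),
                    ".", g.strand, ".", attr]) + "\n")


# ---------------------------------------------------------------------------
# FASTA / sequence access
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def open_fasta(path: str | Path):
    """Open an on-disk FASTA through pyfaidx (lazy, indexed access)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch a sequence slice from a dict-of-str genome or a pyfaidx Fasta.

    Coordinates are clipped to the chromosome.
    """
    record = genome[chrom]
    n = len(record)
    s, e = max(start, 0), min(end, n)
    if s >= e:
        return ""
    return str(record[s:e]).upper()


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = np.asarray(track.data[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int],
                  library_size: float | None = None) -> SignalTrack:
    data = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in data:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        data[chrom][start:end] = value
    return SignalTrack(data, library_size=library_size)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
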