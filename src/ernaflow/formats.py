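"""Readers and writers for the on-disk formats the pipeline touches.

Supported: BED6 (stranded 5'-end reads and generic regions), ChromHMM-style
BED (state id in the name column), ENCODE narrowPeak, bedGraph, a minimal GTF
dialect (gene_id/transcript_id attributes, exon features) and TSV count
matrices.  Everything is converted to 0-based half-open coordinates on ingest;
GTF, the one 1-based inclusive format, is converted back on egress so that
read-write-read round-trips are identity on records.

Errors are deliberately distinct: :class:`MissingColumnError` for structurally
short lines, :class:`ScoreError` for non-numeric numeric fields, and
:class:`CoordinateError` (an :class:`~ernaflow.intervals.IntervalError`) for
coordinate violations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import (
    STRAND_MINUS,
    STRAND_NONE,
    STRAND_PLUS,
    GenomicInterval,
    IntervalError,
    SegmentationTrack,
)


class FormatError(ValueError):
    """Base class for file-format violations."""


class MissingColumnError(FormatError):
    """A line has fewer columns than the named standard requires."""


class ScoreError(FormatError):
    """A numeric column holds a non-numeric value."""


class CoordinateError(FormatError, IntervalError):
    """Coordinates violate the format's conventions."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakCall:
    """A ChIP/ChIRP peak call (narrowPeak semantics).

    ``fold_enrichment`` is the signal ratio versus input (narrowPeak column 7),
    ``neg_log10_q`` the -log10 q-value (column 9), ``summit_offset`` the bp
    offset of the summit from ``interval.start`` (column 10; None if absent).
    ``read_count`` is used by ChIRP probe pools, ``pool`` labels odd/even/merged
    provenance.
    """

    interval: GenomicInterval
    fold_enrichment: float
    neg_log10_q: float
    summit_offset: int | None = None
    read_count: int | None = None
    name: str = "."
    pool: str | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if self.neg_log10_q < 0:
            raise ValueError("neg_log10_q must be >= 0")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset outside [0, length)")


@dataclass(frozen=True)
class Transcript:
    """One transcript: its span, strand, and exon set.

    The TSS is ``interval.start`` on the + strand and ``interval.end - 1`` on
    the - strand (the last covered base, 0-based).
    """

    transcript_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand == STRAND_NONE:
            raise IntervalError(f"transcript {self.transcript_id} needs a strand")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise IntervalError(
                    f"exon {ex} outside transcript {self.transcript_id}"
                )

    @property
    def tss(self) -> int:
        if self.interval.strand == STRAND_PLUS:
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def span(self) -> GenomicInterval:
        chrom = self.transcripts[0].interval.chrom
        strand = self.transcripts[0].interval.strand
        start = min(t.interval.start for t in self.transcripts)
        end = max(t.interval.end for t in self.transcripts)
        return GenomicInterval(chrom, start, end, strand)


@dataclass(frozen=True)
class Read5p:
    """A stranded nascent-transcription read reduced to its 5' end."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise IntervalError("read position must be >= 0")
        if self.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise IntervalError("read strand must be + or -")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _as_int(value: str, what: str, path: str | Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise CoordinateError(
            f"{path}:{lineno}: non-integer {what}: {value!r}"
        ) from exc


def _as_float(value: str, what: str, path: str | Path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ScoreError(f"{path}:{lineno}: non-numeric {what}: {value!r}") from exc


def _need(cols: list[str], n: int, fmt: str, path: str | Path, lineno: int) -> None:
    if len(cols) < n:
        raise MissingColumnError(
            f"{path}:{lineno}: {fmt} needs {n} columns, found {len(cols)}"
        )


def _normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def read_bed6(path: str | Path, normalize_chroms: bool = False) -> list[GenomicInterval]:
    """Read BED6 records as intervals (name/score columns are optional)."""
    out: list[GenomicInterval] = []
    for lineno, cols in _data_lines(path):
        _need(cols, 3, "BED", path, lineno)
        chrom = _normalize_chrom(cols[0]) if normalize_chroms else cols[0]
        start = _as_int(cols[1], "start", path, lineno)
        end = _as_int(cols[2], "end", path, lineno)
        strand = cols[5] if len(cols) >= 6 else STRAND_NONE
        try:
            out.append(GenomicInterval(chrom, start, end, strand))
        except IntervalError as exc:
            raise CoordinateError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed6(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def read_reads_bed6(path: str | Path) -> list[Read5p]:
    """Read stranded 5'-end reads: BED6 where each record is a 1-bp interval
    at the read's 5' end."""
    reads: list[Read5p] = []
    for lineno, cols in _data_lines(path):
        _need(cols, 6, "BED6", path, lineno)
        start = _as_int(cols[1], "start", path, lineno)
        end = _as_int(cols[2], "end", path, lineno)
        if end != start + 1:
            raise CoordinateError(
                f"{path}:{lineno}: 5'-end read records must be 1 bp wide"
            )
        reads.append(Read5p(cols[0], start, cols[5]))
    return reads


def write_reads_bed6(path: str | Path, reads: Sequence[Read5p]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# ChromHMM BED (state id in the name column, e.g. "4" or "4_Strong_Enhancer")
# ---------------------------------------------------------------------------

_STATE_RE = re.compile(r"^(\d+)")


def read_chromhmm_bed(path: str | Path, cell_line: str | None = None) -> SegmentationTrack:
    segments: list[tuple[GenomicInterval, int]] = []
    for lineno, cols in _data_lines(path):
        _need(cols, 4, "ChromHMM BED", path, lineno)
        start = _as_int(cols[1], "start", path, lineno)
        end = _as_int(cols[2], "end", path, lineno)
        m = _STATE_RE.match(cols[3])
        if m is None:
            raise FormatError(
                f"{path}:{lineno}: state column {cols[3]!r} has no leading integer"
            )
        try:
            segments.append((GenomicInterval(cols[0], start, end), int(m.group(1))))
        except IntervalError as exc:
            raise CoordinateError(f"{path}:{lineno}: {exc}") from exc
    name = cell_line if cell_line is not None else Path(path).stem
    return SegmentationTrack(cell_line=name, segments=segments)


def write_chromhmm_bed(path: str | Path, track: SegmentationTrack) -> None:
    with open(path, "w") as fh:
        for iv, state in track.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> list[PeakCall]:
    """Read ENCODE narrowPeak: col 7 = fold enrichment (signalValue),
    col 9 = -log10 q-value, col 10 = summit offset (-1 = absent)."""
    peaks: list[PeakCall] = []
    for lineno, cols in _data_lines(path):
        _need(cols, 10, "narrowPeak", path, lineno)
        start = _as_int(cols[1], "start", path, lineno)
        end = _as_int(cols[2], "end", path, lineno)
        strand = cols[5] if cols[5] in (STRAND_PLUS, STRAND_MINUS) else STRAND_NONE
        fold = _as_float(cols[6], "signalValue", path, lineno)
        neg_log10_q = _as_float(cols[8], "qValue", path, lineno)
        summit = _as_int(cols[9], "summit", path, lineno)
        try:
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(cols[0], start, end, strand),
                    fold_enrichment=fold,
                    neg_log10_q=neg_log10_q,
                    summit_offset=None if summit < 0 else summit,
                    name=cols[3],
                )
            )
        except (IntervalError, ValueError) as exc:
            raise CoordinateError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(path: str | Path, peaks: Sequence[PeakCall]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.fold_enrichment:g}\t-1\t{p.neg_log10_q:g}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedGraphRecord:
    chrom: str
    start: int
    end: int
    value: float


def read_bedgraph(path: str | Path) -> list[BedGraphRecord]:
    out: list[BedGraphRecord] = []
    for lineno, cols in _data_lines(path):
        _need(cols, 4, "bedGraph", path, lineno)
        start = _as_int(cols[1], "start", path, lineno)
        end = _as_int(cols[2], "end", path, lineno)
        if end <= start or start < 0:
            raise CoordinateError(f"{path}:{lineno}: bad bedGraph span")
        out.append(BedGraphRecord(cols[0], start, end, _as_float(cols[3], "value", path, lineno)))
    return out


def write_bedgraph(path: str | Path, records: Sequence[BedGraphRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk; 0-based half-open in memory)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneAnnotation]:
    """Parse a minimal GTF: transcript and exon features with gene_id and
    transcript_id attributes.  Transcripts lacking an explicit ``transcript``
    feature are inferred from their exon span."""
    tx_span: dict[str, GenomicInterval] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []

    for lineno, cols in _data_lines(path):
        _need(cols, 9, "GTF", path, lineno)
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
        start1 = _as_int(start_s, "start", path, lineno)
        end1 = _as_int(end_s, "end", path, lineno)
        if start1 < 1 or end1 < start1:
            raise CoordinateError(f"{path}:{lineno}: bad 1-based GTF span")
        attrd = dict(_ATTR_RE.findall(attrs))
        if "gene_id" not in attrd or "transcript_id" not in attrd:
            raise MissingColumnError(
                f"{path}:{lineno}: GTF attributes need gene_id and transcript_id"
            )
        tid = attrd["transcript_id"]
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        if tid not in tx_gene:
            tx_gene[tid] = attrd["gene_id"]
            order.append(tid)
        if feature == "transcript":
            tx_span[tid] = iv
        elif feature == "exon":
            tx_exons.setdefault(tid, []).append(iv)

    genes: dict[str, list[Transcript]] = {}
    gene_order: list[str] = []
    for tid in order:
        exons = tuple(sorted(tx_exons.get(tid, []), key=lambda e: e.start))
        span = tx_span.get(tid)
        if span is None:
            if not exons:
                raise FormatError(f"transcript {tid} has neither span nor exons")
            span = GenomicInterval(
                exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
            )
        gid = tx_gene[tid]
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(Transcript(tid, span, exons))
    return [GeneAnnotation(gid, tuple(genes[gid])) for gid in gene_order]


def write_gtf(path: str | Path, annotations: Sequence[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        for gene in annotations:
            for tx in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                iv = tx.interval
                fh.write(
                    f"{iv.chrom}\ternaflow\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{ex.chrom}\ternaflow\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# TSV count matrices
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample integer count matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise MissingColumnError(f"{path}: count matrix has no sample columns")
    try:
        df = df.astype("int64")
    except (TypeError, ValueError) as exc:
        raise ScoreError(f"{path}: counts must be integers") from exc
    if (df.to_numpy() < 0).any():
        raise ScoreError(f"{path}: counts must be non-negative")
    return df


def write_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")
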