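"""Putative-enhancer discovery from chromatin states, ChIP peaks and nascent
transcription.

The filter chain: take the per-base union across cell lines of the
chromatin-segmentation enhancer states (ids 4-7 by default), blacklist
positions within 1 kb of any annotated TSS, drop regions overlapped by
annotated transcripts on both strands, require at least one p300 and one Pol2
peak per region, extend the survivors by 1 kb and count stranded nascent-read
5' ends per sample, and keep regions with detectable transcription on both
strands.  The blacklist and cofactor steps are pure region filters, so their
relative order does not change the final set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GeneAnnotation, PeakCall, Read5p
from .intervals import (
    STRAND_MINUS,
    STRAND_PLUS,
    GenomicInterval,
    SegmentationTrack,
    merge_intervals,
    subtract_intervals,
)

log = logging.getLogger(__name__)

DEFAULT_ENHANCER_STATES = frozenset({4, 5, 6, 7})
DEFAULT_TSS_FLANK = 1000
DEFAULT_COUNT_FLANK = 1000
DEFAULT_MIN_STRAND_READS = 1


@dataclass
class CandidateRegion:
    """A candidate enhancer region with its counting window and read counts.

    ``counts`` maps sample id -> (plus_count, minus_count) over the extended
    interval; filled in by :func:`count_stranded_reads`.
    """

    interval: GenomicInterval
    extended_interval: GenomicInterval
    has_p300: bool = False
    has_pol2: bool = False
    cell_lines_supporting: tuple[str, ...] = ()
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ei, iv = self.extended_interval, self.interval
        if not (ei.chrom == iv.chrom and ei.start <= iv.start and ei.end >= iv.end):
            raise ValueError("extended_interval must contain interval")

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    def strand_total(self, strand: str) -> int:
        idx = 0 if strand == STRAND_PLUS else 1
        return sum(c[idx] for c in self.counts.values())


def union_enhancer_states(
    tracks: Sequence[SegmentationTrack],
    enhancer_state_ids: Iterable[int] = DEFAULT_ENHANCER_STATES,
) -> list[GenomicInterval]:
    """Merge, across all cell lines, every position carrying an enhancer state
    in at least one line.  Requested state ids absent from every track are
    warned about and ignored."""
    if not tracks:
        raise ValueError("at least one segmentation track required")
    wanted = set(enhancer_state_ids)
    present: set[int] = set()
    for t in tracks:
        present |= t.states_present()
    unknown = wanted - present
    if unknown:
        log.warning("enhancer state ids absent from all tracks: %s", sorted(unknown))
    pieces: list[GenomicInterval] = []
    for t in tracks:
        pieces.extend(t.intervals_for_states(wanted))
    return merge_intervals(pieces)


def build_blacklist(
    annotations: Sequence[GeneAnnotation], flank: int = DEFAULT_TSS_FLANK
) -> list[GenomicInterval]:
    """Positions within ``flank`` bp of any transcript TSS: the merged union
    of symmetric windows ``[tss - flank, tss + flank + 1)``."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows = []
    for gene in annotations:
        for tx in gene.transcripts:
            tss = tx.tss
            windows.append(
                GenomicInterval(tx.interval.chrom, max(0, tss - flank), tss + flank + 1)
            )
    return merge_intervals(windows)


def _transcript_spans(annotations: Sequence[GeneAnnotation], strand: str) -> list[GenomicInterval]:
    return merge_intervals(
        tx.interval
        for gene in annotations
        for tx in gene.transcripts
        if tx.interval.strand == strand
    )


def drop_bidirectionally_annotated(
    regions: Sequence[GenomicInterval], annotations: Sequence[GeneAnnotation]
) -> list[GenomicInterval]:
    """Remove regions overlapped by annotated transcripts on *both* strands
    (their nascent signal would look bidirectional without being enhancer)."""
    plus = _transcript_spans(annotations, STRAND_PLUS)
    minus = _transcript_spans(annotations, STRAND_MINUS)

    def hits(region: GenomicInterval, spans: list[GenomicInterval]) -> bool:
        return any(region.overlaps(s) for s in spans)

    return [r for r in regions if not (hits(r, plus) and hits(r, minus))]


def require_cofactor_peaks(
    regions: Sequence[GenomicInterval],
    p300_peaks: Sequence[PeakCall],
    pol2_peaks: Sequence[PeakCall],
) -> list[CandidateRegion]:
    """Keep regions overlapped (>= 1 bp) by at least one p300 AND one Pol2 peak."""
    p300 = [p.interval for p in p300_peaks]
    pol2 = [p.interval for p in pol2_peaks]
    out = []
    for r in regions:
        has_p300 = any(r.overlaps(p) for p in p300)
        has_pol2 = any(r.overlaps(p) for p in pol2)
        if has_p300 and has_pol2:
            out.append(
                CandidateRegion(
                    interval=r, extended_interval=r, has_p300=True, has_pol2=True
                )
            )
    return out


class ReadIndex:
    """Sorted per-(chromosome, strand) 5'-end positions for O(log n) counting."""

    def __init__(self, reads: Iterable[Read5p]):
        buckets: dict[tuple[str, str], list[int]] = {}
        self.n_reads = 0
        for r in reads:
            buckets.setdefault((r.chrom, r.strand), []).append(r.pos)
            self.n_reads += 1
        self._arr = {k: np.sort(np.array(v, dtype=np.int64)) for k, v in buckets.items()}

    def count(self, chrom: str, start: int, end: int, strand: str) -> int:
        arr = self._arr.get((chrom, strand))
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def positions(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        arr = self._arr.get((chrom, strand))
        if arr is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(arr, (start, end))
        return arr[lo:hi]


def count_stranded_reads(
    candidates: Sequence[CandidateRegion],
    reads_by_sample: Mapping[str, Sequence[Read5p] | ReadIndex],
    flank: int = DEFAULT_COUNT_FLANK,
    known_chroms: set[str] | None = None,
) -> list[CandidateRegion]:
    """Extend each region by ``flank`` bp and count 5' ends per strand per
    sample; a read is counted once per region whose extended window contains
    its 5'-end position."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    indexes: dict[str, ReadIndex] = {}
    for sample, reads in reads_by_sample.items():
        idx = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
        indexes[sample] = idx
        if known_chroms is not None and not isinstance(reads, ReadIndex):
            skipped = {r.chrom for r in reads} - known_chroms
            if skipped:
                log.warning("sample %s: reads on unknown chromosomes %s skipped",
                            sample, sorted(skipped))
    out = []
    for cand in candidates:
        ext = cand.interval.expanded(flank)
        counts = {
            sample: (
                idx.count(ext.chrom, ext.start, ext.end, STRAND_PLUS),
                idx.count(ext.chrom, ext.start, ext.end, STRAND_MINUS),
            )
            for sample, idx in indexes.items()
        }
        out.append(
            CandidateRegion(
                interval=cand.interval,
                extended_interval=ext,
                has_p300=cand.has_p300,
                has_pol2=cand.has_pol2,
                cell_lines_supporting=cand.cell_lines_supporting,
                counts=counts,
            )
        )
    return out


def require_bidirectional(
    candidates: Sequence[CandidateRegion],
    min_reads_per_strand: int = DEFAULT_MIN_STRAND_READS,
) -> list[CandidateRegion]:
    """Keep regions with detectable transcription on both strands: at least
    ``min_reads_per_strand`` 5' ends per strand, pooled across all samples."""
    if min_reads_per_strand < 1:
        raise ValueError("min_reads_per_strand must be >= 1")
    return [
        c
        for c in candidates
        if c.strand_total(STRAND_PLUS) >= min_reads_per_strand
        and c.strand_total(STRAND_MINUS) >= min_reads_per_strand
    ]


def collapse_transcripts(annotations: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """Collapse same-strand overlapping transcripts into omnibus loci.

    Transcripts whose spans overlap on the same strand become one locus whose
    exon set is the per-base union of member exons; opposite strands never
    merge.  Collapsed loci are named after their member gene ids.
    """
    from .formats import Transcript  # local import to avoid cycle at module load

    by_strand: dict[str, list[tuple[GeneAnnotation, Transcript]]] = {"+": [], "-": []}
    for gene in annotations:
        for tx in gene.transcripts:
            by_strand[tx.interval.strand].append((gene, tx))

    out: list[GeneAnnotation] = []
    for strand, members in by_strand.items():
        members.sort(key=lambda gt: (gt[1].interval.chrom, gt[1].interval.start))
        cluster: list[tuple[GeneAnnotation, Transcript]] = []

        def flush() -> None:
            if not cluster:
                return
            gene_ids = sorted({g.gene_id for g, _t in cluster})
            txs = [t for _g, t in cluster]
            chrom = txs[0].interval.chrom
            span = GenomicInterval(
                chrom,
                min(t.interval.start for t in txs),
                max(t.interval.end for t in txs),
                strand,
            )
            exon_union = merge_intervals(ex for t in txs for ex in t.exons)
            locus_id = "|".join(gene_ids)
            out.append(
                GeneAnnotation(
                    gene_id=locus_id,
                    transcripts=(
                        Transcript(
                            transcript_id=f"{locus_id}.omnibus",
                            interval=span,
                            exons=tuple(
                                GenomicInterval(e.chrom, e.start, e.end, strand)
                                for e in exon_union
                            ),
                        ),
                    ),
                )
            )

        span_end = -1
        span_chrom = ""
        for gene, tx in members:
            iv = tx.interval
            if cluster and iv.chrom == span_chrom and iv.start < span_end:
                cluster.append((gene, tx))
                span_end = max(span_end, iv.end)
            else:
                flush()
                cluster = [(gene, tx)]
                span_chrom, span_end = iv.chrom, iv.end
        flush()
    out.sort(key=lambda g: (g.span.chrom, g.span.start))
    return out


def call_enhancers(
    tracks: Sequence[SegmentationTrack],
    annotations: Sequence[GeneAnnotation],
    p300_peaks: Sequence[PeakCall],
    pol2_peaks: Sequence[PeakCall],
    reads_by_sample: Mapping[str, Sequence[Read5p] | ReadIndex],
    enhancer_state_ids: Iterable[int] = DEFAULT_ENHANCER_STATES,
    tss_flank: int = DEFAULT_TSS_FLANK,
    count_flank: int = DEFAULT_COUNT_FLANK,
    min_reads_per_strand: int = DEFAULT_MIN_STRAND_READS,
    blacklist_mode: str = "position",
) -> list[CandidateRegion]:
    """Run the full discovery chain and return bidirectionally transcribed
    candidate enhancer regions with per-sample per-strand counts.

    ``blacklist_mode`` "position" trims blacklisted bases out of regions
    (fragments survive); "region" drops any region touching the blacklist.
    """
    regions = union_enhancer_states(tracks, enhancer_state_ids)
    blacklist = build_blacklist(annotations, tss_flank)
    if blacklist_mode == "position":
        regions = subtract_intervals(regions, blacklist)
    elif blacklist_mode == "region":
        regions = [r for r in regions if not any(r.overlaps(b) for b in blacklist)]
    else:
        raise ValueError("blacklist_mode must be 'position' or 'region'")
    regions = drop_bidirectionally_annotated(regions, annotations)
    candidates = require_cofactor_peaks(regions, p300_peaks, pol2_peaks)
    candidates = count_stranded_reads(candidates, reads_by_sample, count_flank)
    return require_bidirectional(candidates, min_reads_per_strand)


def counts_to_matrices(
    candidates: Sequence[CandidateRegion],
    conditions: Mapping[str, str],
    library_sizes: Mapping[str, float] | None = None,
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Per-strand count matrices (plus, minus) indexed by region id."""
    samples = sorted(conditions)
    plus = pd.DataFrame(
        {s: [c.counts.get(s, (0, 0))[0] for c in candidates] for s in samples},
        index=[c.region_id for c in candidates],
        dtype="int64",
    )
    minus = pd.DataFrame(
        {s: [c.counts.get(s, (0, 0))[1] for c in candidates] for s in samples},
        index=[c.region_id for c in candidates],
        dtype="int64",
    )
    return plus, minus
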