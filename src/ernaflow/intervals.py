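"""Strand-aware genomic interval algebra.

All coordinates are 0-based half-open (BED convention): an interval
``chr1:100-200`` covers bases 100..199.  GTF input is converted at the file
boundary (see :mod:`ernaflow.formats`).  Two intervals that merely touch
(``a.end == b.start``) share no base but are merged by :func:`merge_intervals`,
because a zero-length gap is no gap when intervals describe position sets.

Set operations here are unstranded: strand is carried along on the records
that need it (reads, transcripts, peaks) but merge/subtract/intersect act on
positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_PLUS, STRAND_MINUS, STRAND_NONE})


class IntervalError(ValueError):
    """A malformed genomic interval (end <= start, negative start, ...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    Parameters
    ----------
    chrom:
        Chromosome name; compared by exact string match (no "chr" aliasing).
    start, end:
        0-based half-open coordinates, ``0 <= start < end``.
    strand:
        ``"+"``, ``"-"`` or ``"."`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chromosome name must be non-empty")
        if self.start < 0:
            raise IntervalError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 for overlapping or abutting intervals.

        Raises :class:`IntervalError` for intervals on different chromosomes,
        where a base-pair distance is undefined.
        """
        if self.chrom != other.chrom:
            raise IntervalError(
                f"gap undefined across chromosomes {self.chrom}/{other.chrom}"
            )
        return max(0, max(self.start - other.end, other.start - self.end))

    def expanded(self, slop: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Symmetrically extend by ``slop`` bp, clipped at 0 (and chrom end)."""
        if slop < 0:
            raise IntervalError("slop must be >= 0")
        end = self.end + slop
        if chrom_length is not None:
            end = min(end, chrom_length)
        return replace(self, start=max(0, self.start - slop), end=end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == STRAND_NONE else f"{s}({self.strand})"


def _sorted_by_position(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and touching* intervals into a disjoint sorted list.

    The per-base union of the output equals that of the input; strand
    information is discarded (output intervals are unstranded).
    """
    ivs = _sorted_by_position(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def subtract_intervals(
    intervals: Iterable[GenomicInterval], mask: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base set difference ``intervals \\ mask``.

    Fully masked intervals disappear; partial overlap trims or splits.
    Strand of surviving fragments follows the source interval.
    """
    mask_by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in merge_intervals(mask):
        mask_by_chrom.setdefault(m.chrom, []).append(m)

    out: list[GenomicInterval] = []
    for iv in _sorted_by_position(intervals):
        cursor = iv.start
        for m in mask_by_chrom.get(iv.chrom, ()):
            if m.end <= cursor:
                continue
            if m.start >= iv.end:
                break
            if m.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, m.start, iv.strand))
            cursor = max(cursor, m.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.strand))
    return out


def intersect_intervals(
    intervals: Iterable[GenomicInterval], other: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base intersection; together with subtract it partitions the bases."""
    other_by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in merge_intervals(other):
        other_by_chrom.setdefault(m.chrom, []).append(m)

    out: list[GenomicInterval] = []
    for iv in _sorted_by_position(intervals):
        for m in other_by_chrom.get(iv.chrom, ()):
            lo, hi = max(iv.start, m.start), min(iv.end, m.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi, iv.strand))
            if m.start >= iv.end:
                break
    return out


def overlaps_any(
    query: GenomicInterval,
    subjects: Iterable[GenomicInterval],
    slop: int = 0,
) -> bool:
    """True iff some subject, extended symmetrically by ``slop`` bp, shares
    at least one base with ``query``.  Half-open: abutment is not overlap."""
    if slop < 0:
        raise IntervalError("slop must be >= 0")
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if max(0, s.start - slop) < query.end and query.start < s.end + slop:
            return True
    return False


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered (computed on the merged union)."""
    return sum(iv.length for iv in merge_intervals(intervals))


@dataclass
class SegmentationTrack:
    """A ChromHMM-style chromatin-state segmentation for one cell line.

    ``segments`` is a list of ``(interval, state_id)`` sorted by
    ``(chrom, start)`` with no same-chromosome overlap; state ids are the
    small integers of the segmentation (enhancer classes are 4-7 in the
    nine-cell-line track this models).
    """

    cell_line: str
    segments: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s[0].chrom, s[0].start, s[0].end)
        )
        prev: GenomicInterval | None = None
        for iv, _state in self.segments:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise IntervalError(
                    f"overlapping segments in track {self.cell_line}: "
                    f"{prev} / {iv}"
                )
            prev = iv

    def states_present(self) -> set[int]:
        return {state for _iv, state in self.segments}

    def intervals_for_states(self, state_ids: Sequence[int] | set[int]) -> list[GenomicInterval]:
        wanted = set(state_ids)
        return [iv for iv, state in self.segments if state in wanted]

    def state_at(self, chrom: str, pos: int) -> int | None:
        """State covering a single base, or None if uncovered."""
        for iv, state in self.segments:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return state
        return None
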