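"""Reconciliation of lncRNA ChIRP peaks from the odd and even probe pools,
and enrichment of the reconciled binding sites in chromatin states and in
regulated-enhancer sets.

A binding site is trusted only if it replicates across the two independent
antisense probe pools: peaks from both pools must overlap, their per-base
coverage over the union span must correlate (Pearson r >= 0.2), each pool
must contribute at least 25 reads over that span, and known plasmid
contaminants are removed.  Coverage is interpreted as 5'-end counts per base,
so the coverage sum over a span equals the read count on that span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .formats import BedGraphRecord, PeakCall
from .intervals import GenomicInterval, SegmentationTrack, merge_intervals

log = logging.getLogger(__name__)

DEFAULT_MIN_NEG_LOG10_Q = 5.0
DEFAULT_MIN_ENRICHMENT = 4.0
DEFAULT_MIN_CORRELATION = 0.2
DEFAULT_MIN_READS = 25

ODD = "odd"
EVEN = "even"
MERGED = "merged"


def filter_chirp_peaks(
    peaks: Sequence[PeakCall],
    min_neg_log10_q: float = DEFAULT_MIN_NEG_LOG10_Q,
    min_enrichment: float = DEFAULT_MIN_ENRICHMENT,
) -> list[PeakCall]:
    """Keep peaks with -log10(q) >= 5 and enrichment >= 4 (inclusive)."""
    if min_neg_log10_q < 0 or min_enrichment < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        p
        for p in peaks
        if p.neg_log10_q >= min_neg_log10_q and p.fold_enrichment >= min_enrichment
    ]


class CoverageTrack:
    """Random access to per-base coverage from bedGraph records."""

    def __init__(self, records: Sequence[BedGraphRecord]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[BedGraphRecord]] = {}
        for r in records:
            grouped.setdefault(r.chrom, []).append(r)
        for chrom, recs in grouped.items():
            recs.sort(key=lambda r: r.start)
            self._by_chrom[chrom] = (
                np.array([r.start for r in recs], dtype=np.int64),
                np.array([r.end for r in recs], dtype=np.int64),
                np.array([r.value for r in recs], dtype=float),
            )

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._by_chrom:
            return out
        starts, ends, values = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a, b = max(starts[i], start), min(ends[i], end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out

    def read_count(self, chrom: str, start: int, end: int) -> float:
        """Sum of coverage over the span (= read count for 5'-end coverage)."""
        return float(self.per_base(chrom, start, end).sum())


@dataclass
class MergedPeak:
    """A reconciled binding site with provenance from both pools."""

    interval: GenomicInterval
    source_odd: tuple[int, ...]
    source_even: tuple[int, ...]
    correlation: float
    reads_odd: float
    reads_even: float

    def __post_init__(self) -> None:
        if not self.source_odd or not self.source_even:
            raise ValueError("merged peak must trace to both pools")


@dataclass
class ChirpPeakSet:
    odd_peaks: list[PeakCall]
    even_peaks: list[PeakCall]
    merged: list[MergedPeak] = field(default_factory=list)
    contaminant_blacklist: list[GenomicInterval] = field(default_factory=list)


def reconcile_pools(
    odd_peaks: Sequence[PeakCall],
    even_peaks: Sequence[PeakCall],
    odd_coverage: CoverageTrack,
    even_coverage: CoverageTrack,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
    min_reads: float = DEFAULT_MIN_READS,
) -> list[MergedPeak]:
    """Merge replicated odd/even peak pairs into binding sites.

    Every overlapping odd/even pair is a candidate.  Over the union span of
    the pair, the two pools' per-base coverage vectors must reach a Pearson
    correlation of at least ``min_correlation`` and each pool must hold at
    least ``min_reads`` reads; zero-variance coverage on either pool makes
    the correlation undefined and rejects the pair.  Passing pairs are merged
    into the union of their spans, transitively when they share a source peak.
    """
    passing: list[tuple[int, int, GenomicInterval, float, float, float]] = []
    for i, op in enumerate(odd_peaks):
        for j, ep in enumerate(even_peaks):
            if not op.interval.overlaps(ep.interval):
                continue
            span = GenomicInterval(
                op.interval.chrom,
                min(op.interval.start, ep.interval.start),
                max(op.interval.end, ep.interval.end),
            )
            ov = odd_coverage.per_base(span.chrom, span.start, span.end)
            ev = even_coverage.per_base(span.chrom, span.start, span.end)
            if ov.std() == 0.0 or ev.std() == 0.0:
                log.info("pair odd[%d]/even[%d] rejected: zero-variance coverage", i, j)
                continue
            r = float(stats.pearsonr(ov, ev).statistic)
            reads_odd, reads_even = float(ov.sum()), float(ev.sum())
            if r >= min_correlation and reads_odd >= min_reads and reads_even >= min_reads:
                passing.append((i, j, span, r, reads_odd, reads_even))
            else:
                log.info(
                    "pair odd[%d]/even[%d] rejected: r=%.3f reads=(%.0f, %.0f)",
                    i, j, r, reads_odd, reads_even,
                )

    # transitive merge: pairs sharing a source peak overlap through that
    # peak's span, so merging union spans realizes the transitivity
    merged_spans = merge_intervals(p[2] for p in passing)
    out = []
    for span in merged_spans:
        members = [p for p in passing if span.overlaps(p[2])]
        out.append(
            MergedPeak(
                interval=span,
                source_odd=tuple(sorted({p[0] for p in members})),
                source_even=tuple(sorted({p[1] for p in members})),
                correlation=max(p[3] for p in members),
                reads_odd=odd_coverage.read_count(span.chrom, span.start, span.end),
                reads_even=even_coverage.read_count(span.chrom, span.start, span.end),
            )
        )
    return out


def remove_contaminants(
    peaks: Sequence[MergedPeak], blacklist: Sequence[GenomicInterval]
) -> list[MergedPeak]:
    """Drop any merged peak overlapping a known contaminant interval
    (any-overlap rule: partial overlap removes the peak)."""
    return [
        p
        for p in peaks
        if not any(p.interval.overlaps(b) for b in blacklist)
    ]


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    expected: float
    fold: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold < 0 or not (0 <= self.p_value <= 1):
            raise ValueError("invalid enrichment result")


def state_enrichment(
    peaks: Sequence[MergedPeak], segmentation: SegmentationTrack
) -> list[EnrichmentResult]:
    """Enrichment of binding sites in each chromatin state.

    Each peak is assigned to the state covering its midpoint; the expected
    count for a state is ``n_peaks * state_bp / total_bp`` and the p-value is
    the binomial upper tail ``P(X >= observed)`` with success probability
    ``state_bp / total_bp``.  Peaks whose midpoint falls outside the
    segmentation are ignored with a warning.
    """
    state_bp: dict[int, int] = {}
    for iv, state in segmentation.segments:
        state_bp[state] = state_bp.get(state, 0) + iv.length
    total = sum(state_bp.values())
    if total == 0:
        raise ValueError("empty segmentation")

    observed: dict[int, int] = {s: 0 for s in state_bp}
    n_assigned = 0
    for p in peaks:
        state = segmentation.state_at(p.interval.chrom, p.interval.midpoint)
        if state is None:
            log.warning("peak %s midpoint outside segmentation; ignored", p.interval)
            continue
        observed[state] += 1
        n_assigned += 1

    out = []
    for state in sorted(state_bp):
        frac = state_bp[state] / total
        if state_bp[state] == 0:
            continue
        obs = observed[state]
        expected = n_assigned * frac
        fold = obs / expected if expected > 0 else 0.0
        p_value = float(stats.binom.sf(obs - 1, n_assigned, frac)) if n_assigned else 1.0
        out.append(
            EnrichmentResult(
                category=f"state_{state}",
                observed=obs,
                expected=expected,
                fold=fold,
                p_value=min(1.0, p_value),
            )
        )
    return out


def bound_enhancer_enrichment(
    bound_ids: set[str], induced_ids: set[str], universe_ids: set[str]
) -> EnrichmentResult:
    """Hypergeometric enrichment of induced enhancers among lncRNA-bound ones.

    With population ``|universe|``, ``|induced|`` successes and ``|bound|``
    draws, returns the upper tail ``P(X >= overlap)`` where the overlap is
    ``|bound & induced|``.
    """
    if not universe_ids:
        raise ValueError("empty universe")
    if not bound_ids <= universe_ids or not induced_ids <= universe_ids:
        raise ValueError("bound and induced sets must be subsets of the universe")
    m, n_succ, n_draw = len(universe_ids), len(induced_ids), len(bound_ids)
    overlap = len(bound_ids & induced_ids)
    expected = n_draw * n_succ / m
    p = float(stats.hypergeom.sf(overlap - 1, m, n_succ, n_draw))
    return EnrichmentResult(
        category="induced_in_bound",
        observed=overlap,
        expected=expected,
        fold=overlap / expected if expected > 0 else 0.0,
        p_value=min(1.0, p),
    )
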