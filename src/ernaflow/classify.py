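"""Classification of regulated enhancers by p53 binding and descriptive
geometry: bound (BER) versus free (FER) split, the midpoint of bidirectional
transcription, downstream drop-off profiles, nearest-gene distances, and the
motif-window / background extraction used for sequence enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import CandidateRegion, ReadIndex
from .formats import GeneAnnotation, PeakCall
from .intervals import STRAND_MINUS, STRAND_PLUS, GenomicInterval

log = logging.getLogger(__name__)

BER = "BER"  # p53-bound enhancer region
FER = "FER"  # p53-free enhancer region

DEFAULT_MIN_FOLD = 3.0
DEFAULT_MIN_NEG_LOG10_Q = 2.0
DEFAULT_P53_WINDOW = 1000
DEFAULT_MOTIF_WIDTH = 200
DEFAULT_BACKGROUND_FDR_FLOOR = 0.75


class UnidirectionalRegionError(ValueError):
    """Raised when a midpoint is requested for a region lacking reads on one
    strand: the midpoint of bidirectional transcription is undefined there."""


def filter_tf_peaks(
    peaks: Sequence[PeakCall],
    min_fold: float = DEFAULT_MIN_FOLD,
    min_neg_log10_q: float = DEFAULT_MIN_NEG_LOG10_Q,
) -> list[PeakCall]:
    """Discard peaks with fold enrichment or -log10(q) strictly below the
    thresholds (defaults 3.0 and 2.0; equality survives)."""
    if min_fold < 0 or min_neg_log10_q < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        p
        for p in peaks
        if p.fold_enrichment >= min_fold and p.neg_log10_q >= min_neg_log10_q
    ]


@dataclass
class ClassifiedEnhancer:
    region: CandidateRegion
    p53_class: str  # BER or FER
    midpoint: int | None = None
    dropoff_q75_distance: float | None = None
    nearest_induced_gene_distance: int | None = None
    nearest_nonregulated_gene_distance: int | None = None

    def __post_init__(self) -> None:
        if self.p53_class not in (BER, FER):
            raise ValueError(f"p53_class must be {BER} or {FER}")
        if self.midpoint is not None:
            ext = self.region.extended_interval
            if not (ext.start <= self.midpoint < ext.end):
                raise ValueError("midpoint outside extended interval")


def assign_p53_class(
    enhancers: Sequence[CandidateRegion],
    p53_peaks: Sequence[PeakCall],
    window: int = DEFAULT_P53_WINDOW,
) -> list[ClassifiedEnhancer]:
    """BER iff a (pre-filtered) p53 peak lies within ``window`` bp of the
    region: edge-to-edge gap <= window, overlap counting as gap 0 (the
    boundary is inclusive, so a gap of exactly 1000 is still bound)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in p53_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    out = []
    for enh in enhancers:
        iv = enh.interval
        bound = any(iv.gap_to(p) <= window for p in by_chrom.get(iv.chrom, ()))
        out.append(ClassifiedEnhancer(region=enh, p53_class=BER if bound else FER))
    return out


def bidirectional_midpoint(
    enhancer: CandidateRegion, pooled_treated_reads: ReadIndex
) -> int:
    """The point separating minus-strand (upstream) from plus-strand
    (downstream) transcription.

    Over the extended interval, returns the position p minimizing the number
    of misplaced 5' ends, ``#{plus < p} + #{minus >= p}``; ties break to the
    smallest p.  The objective only changes at read positions, so the scan
    runs over ``ext.start`` and ``pos + 1`` for each read position.
    """
    ext = enhancer.extended_interval
    plus = pooled_treated_reads.positions(ext.chrom, ext.start, ext.end, STRAND_PLUS)
    minus = pooled_treated_reads.positions(ext.chrom, ext.start, ext.end, STRAND_MINUS)
    if len(plus) == 0 or len(minus) == 0:
        raise UnidirectionalRegionError(
            f"{enhancer.region_id}: no reads on both strands in treated pool"
        )
    candidates = np.unique(np.concatenate([[ext.start], plus + 1, minus + 1]))
    candidates = candidates[(candidates >= ext.start) & (candidates < ext.end)]
    misplaced = np.searchsorted(plus, candidates) + (
        len(minus) - np.searchsorted(minus, candidates)
    )
    best = int(np.argmin(misplaced))  # argmin takes the first = smallest p
    return int(candidates[best])


def dropoff_profile(
    enhancers: Sequence[ClassifiedEnhancer],
    reads: ReadIndex,
    bin_bp: int = 100,
    max_bp: int = 2000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median normalized density of transcription downstream of the midpoint.

    For each enhancer, plus-strand 5' ends at/after the midpoint and
    minus-strand 5' ends before it are both oriented "downstream", binned in
    ``bin_bp`` steps out to ``max_bp``, and normalized to unit mass per
    enhancer before the per-bin median is taken across enhancers of each
    class.  The per-enhancer q75 distance is the upper edge of the first bin
    where the cumulative density reaches 0.75.

    Returns ``(median_profiles, q75_distances)``: a class x bin frame of
    median densities and a per-enhancer Series of q75 distances (bp).
    """
    if bin_bp <= 0 or max_bp <= 0 or max_bp % bin_bp:
        raise ValueError("bins must be positive and max_bp a multiple of bin_bp")
    n_bins = max_bp // bin_bp
    edges = np.arange(0, max_bp + bin_bp, bin_bp)

    rows: dict[str, np.ndarray] = {}
    q75: dict[str, float] = {}
    classes: dict[str, str] = {}
    for enh in enhancers:
        if enh.midpoint is None:
            raise ValueError(f"{enh.region.region_id}: midpoint not set")
        ext = enh.region.extended_interval
        mid = enh.midpoint
        plus = reads.positions(ext.chrom, mid, mid + max_bp, STRAND_PLUS)
        minus = reads.positions(ext.chrom, max(0, mid - max_bp), mid, STRAND_MINUS)
        dist = np.concatenate([plus - mid, mid - 1 - minus])
        if len(dist) == 0:
            log.warning("%s: no reads within %d bp of midpoint; skipped",
                        enh.region.region_id, max_bp)
            continue
        hist, _ = np.histogram(dist, bins=edges)
        density = hist / hist.sum()
        rid = enh.region.region_id
        rows[rid] = density
        classes[rid] = enh.p53_class
        cum = np.cumsum(density)
        q75[rid] = float(edges[1:][int(np.argmax(cum >= 0.75))])

    if not rows:
        return (
            pd.DataFrame(columns=[f"bin_{e}" for e in edges[1:]]),
            pd.Series(dtype=float, name="q75_distance"),
        )
    dens = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"bin_{e}" for e in edges[1:]])
    dens["p53_class"] = pd.Series(classes)
    medians = dens.groupby("p53_class").median()
    return medians, pd.Series(q75, name="q75_distance")


def nearest_gene_distances(
    enhancers: Sequence[ClassifiedEnhancer],
    genes_induced: Sequence[GeneAnnotation],
    genes_nonregulated: Sequence[GeneAnnotation],
    anchor: str = "body",
) -> pd.DataFrame:
    """Edge-to-edge gap (0 if overlapping) from each enhancer region to the
    nearest gene in each set; ``anchor`` "tss" measures to the TSS base
    instead of the gene body.  Empty gene sets yield NaN distances."""
    ind_ids = {g.gene_id for g in genes_induced}
    if ind_ids & {g.gene_id for g in genes_nonregulated}:
        raise ValueError("induced and non-regulated gene sets must be disjoint")

    def anchors(genes: Sequence[GeneAnnotation]) -> dict[str, list[GenomicInterval]]:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for g in genes:
            if anchor == "body":
                iv = g.span
            elif anchor == "tss":
                tss = g.transcripts[0].tss
                iv = GenomicInterval(g.span.chrom, tss, tss + 1)
            else:
                raise ValueError("anchor must be 'body' or 'tss'")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        return by_chrom

    ind = anchors(genes_induced)
    non = anchors(genes_nonregulated)
    if not genes_induced or not genes_nonregulated:
        log.warning("empty gene set: distances reported as NaN")

    def nearest(iv: GenomicInterval, pool: dict[str, list[GenomicInterval]]) -> float:
        spans = pool.get(iv.chrom, ())
        if not spans:
            return float("nan")
        return float(min(iv.gap_to(s) for s in spans))

    rows = []
    for enh in enhancers:
        iv = enh.region.interval
        rows.append(
            {
                "region_id": enh.region.region_id,
                "p53_class": enh.p53_class,
                "dist_induced_gene": nearest(iv, ind),
                "dist_nonregulated_gene": nearest(iv, non),
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def extract_motif_windows(
    enhancers: Sequence[ClassifiedEnhancer],
    genome_sequence: Mapping[str, str],
    width: int = DEFAULT_MOTIF_WIDTH,
) -> list[tuple[str, str]]:
    """DNA windows of ``width`` bp centred on each midpoint of bidirectional
    transcription: ``[midpoint - width/2, midpoint + width/2)``, truncated
    (with a warning) at chromosome ends.  Returns (region_id, sequence)."""
    if width <= 0 or width % 2:
        raise ValueError("width must be positive and even")
    out = []
    for enh in enhancers:
        if enh.midpoint is None:
            raise ValueError(f"{enh.region.region_id}: midpoint not set")
        chrom = enh.region.interval.chrom
        seq = genome_sequence[chrom]
        lo = enh.midpoint - width // 2
        hi = enh.midpoint + width // 2
        if lo < 0 or hi > len(seq):
            log.warning("%s: motif window truncated at chromosome edge",
                        enh.region.region_id)
            lo, hi = max(0, lo), min(len(seq), hi)
        out.append((enh.region.region_id, seq[lo:hi]))
    return out


def write_fasta(path: str, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def select_backgrounds(
    all_enhancers: Sequence[CandidateRegion],
    plus_fdr: Mapping[str, float],
    minus_fdr: Mapping[str, float],
    p53_peaks: Sequence[PeakCall],
    fdr_floor: float = DEFAULT_BACKGROUND_FDR_FLOOR,
    p53_exclusion_window: int = DEFAULT_P53_WINDOW,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Motif-search backgrounds: unresponsive bidirectional enhancers.

    The BER background contains enhancers whose differential-expression FDR is
    >= ``fdr_floor`` on *both* strands; the FER background additionally
    excludes enhancers with a p53 peak within ``p53_exclusion_window`` bp.
    Returns ``(ber_background, fer_background)``.
    """
    quiet = [
        e
        for e in all_enhancers
        if plus_fdr.get(e.region_id, 0.0) >= fdr_floor
        and minus_fdr.get(e.region_id, 0.0) >= fdr_floor
    ]
    labelled = assign_p53_class(quiet, p53_peaks, p53_exclusion_window)
    fer_background = [c.region for c in labelled if c.p53_class == FER]
    return quiet, fer_background
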