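"""End-to-end driver: discovery -> strand-wise exact tests -> regulation
verdicts -> p53-binding classification, with ground-truth scoring helpers for
simulated datasets."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, diff, discovery
from .diff import CountMatrix, RegulationSummary
from .intervals import GenomicInterval
from .simulate import LABEL_INDUCED, LABEL_REPRESSED, SimulatedDataset


@dataclass
class PipelineResult:
    candidates: list[discovery.CandidateRegion]
    plus_results: pd.DataFrame
    minus_results: pd.DataFrame
    verdicts: pd.Series
    summary: RegulationSummary
    classified: list[classify.ClassifiedEnhancer]
    dispersion: float

    def regions_with_verdict(self, verdict: str) -> list[discovery.CandidateRegion]:
        ids = set(self.verdicts[self.verdicts == verdict].index)
        return [c for c in self.candidates if c.region_id in ids]


def run_pipeline(
    dataset: SimulatedDataset,
    fdr_threshold: float = diff.DEFAULT_FDR,
    min_reads_per_strand: int = discovery.DEFAULT_MIN_STRAND_READS,
) -> PipelineResult:
    """Run discovery, differential testing and p53 classification on a
    simulated dataset (or any dataset exposing the same attributes)."""
    reads_by_sample = {
        s: discovery.ReadIndex(dataset.reads_as_records(s)) for s in dataset.reads
    }
    candidates = discovery.call_enhancers(
        tracks=dataset.tracks,
        annotations=dataset.annotations,
        p300_peaks=dataset.p300_peaks,
        pol2_peaks=dataset.pol2_peaks,
        reads_by_sample=reads_by_sample,
        min_reads_per_strand=min_reads_per_strand,
    )
    plus, minus = discovery.counts_to_matrices(candidates, dataset.conditions)
    lib_sizes = dataset.library_sizes
    plus_m = CountMatrix(plus, dataset.conditions, dict(lib_sizes))
    minus_m = CountMatrix(minus, dataset.conditions, dict(lib_sizes))
    stacked = CountMatrix(
        pd.concat([plus, minus]).set_axis(
            [f"{rid}:+" for rid in plus.index] + [f"{rid}:-" for rid in minus.index]
        ),
        dataset.conditions,
        dict(lib_sizes),
    )
    dispersion = diff.estimate_dispersion(stacked)
    plus_res = diff.exact_test_matrix(plus_m, dispersion)
    minus_res = diff.exact_test_matrix(minus_m, dispersion)
    verdicts, summary = diff.classify_regulation(plus_res, minus_res, fdr_threshold)

    filtered_p53 = classify.filter_tf_peaks(dataset.p53_peaks)
    regulated_ids = set(verdicts[verdicts != diff.UNCHANGED].index)
    regulated = [c for c in candidates if c.region_id in regulated_ids]
    classified = classify.assign_p53_class(regulated, filtered_p53)
    return PipelineResult(
        candidates=candidates,
        plus_results=plus_res,
        minus_results=minus_res,
        verdicts=verdicts,
        summary=summary,
        classified=classified,
        dispersion=dispersion,
    )


# ---------------------------------------------------------------------------
# scoring against planted truth
# ---------------------------------------------------------------------------


def _truth_intervals(truth_frame: pd.DataFrame, label: str | None = None) -> list[GenomicInterval]:
    sub = truth_frame if label is None else truth_frame[truth_frame["label"] == label]
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()
    ]


@dataclass
class RecoveryReport:
    n_planted_induced: int
    n_recovered_induced: int
    n_called_induced: int
    n_false_induced: int

    @property
    def recovery(self) -> float:
        return (
            self.n_recovered_induced / self.n_planted_induced
            if self.n_planted_induced
            else float("nan")
        )

    @property
    def false_discovery_proportion(self) -> float:
        return (
            self.n_false_induced / self.n_called_induced
            if self.n_called_induced
            else 0.0
        )


def score_induced_recovery(
    result: PipelineResult, dataset: SimulatedDataset
) -> RecoveryReport:
    """Planted-truth scoring: an induced call is a true positive iff its
    region overlaps a planted induced enhancer; recovery is the fraction of
    planted induced enhancers overlapped by an induced call."""
    planted = _truth_intervals(dataset.truth.enhancers, LABEL_INDUCED)
    called = [c.interval for c in result.regions_with_verdict(diff.INDUCED)]
    recovered = sum(1 for p in planted if any(p.overlaps(c) for c in called))
    false = sum(1 for c in called if not any(c.overlaps(p) for p in planted))
    return RecoveryReport(
        n_planted_induced=len(planted),
        n_recovered_induced=recovered,
        n_called_induced=len(called),
        n_false_induced=false,
    )


def score_p53_classes(
    result: PipelineResult, dataset: SimulatedDataset
) -> tuple[int, int]:
    """(n_matching, n_scored): candidate regions overlapping exactly one
    planted enhancer whose BER/FER label matches the planted p53_bound flag."""
    bound = _truth_intervals(
        dataset.truth.enhancers[dataset.truth.enhancers["p53_bound"]]
    )
    unbound = _truth_intervals(
        dataset.truth.enhancers[~dataset.truth.enhancers["p53_bound"]]
    )
    n_match = n_scored = 0
    for ce in result.classified:
        iv = ce.region.interval
        is_bound = any(iv.overlaps(p) for p in bound)
        is_unbound = any(iv.overlaps(p) for p in unbound)
        if is_bound == is_unbound:  # no planted overlap, or ambiguous
            continue
        n_scored += 1
        expected = classify.BER if is_bound else classify.FER
        if ce.p53_class == expected:
            n_match += 1
    return n_match, n_scored


def score_regulated_fraction(result: PipelineResult) -> float:
    """Fraction of tested enhancers called regulated (any verdict but
    unchanged); under a null simulation this calibrates against the FDR."""
    if result.summary.n_features == 0:
        return 0.0
    return result.summary.n_regulated / result.summary.n_features
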