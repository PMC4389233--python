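"""The enhancer filter chain: state union, TSS blacklist, annotation drops,
cofactor requirement, stranded counting and bidirectionality."""

import numpy as np
import pytest

from ernaflow.discovery import (
    CandidateRegion,
    ReadIndex,
    build_blacklist,
    call_enhancers,
    collapse_transcripts,
    count_stranded_reads,
    drop_bidirectionally_annotated,
    require_bidirectional,
    require_cofactor_peaks,
    union_enhancer_states,
)
from ernaflow.formats import GeneAnnotation, PeakCall, Read5p, Transcript
from ernaflow.intervals import GenomicInterval, SegmentationTrack
from oracles import bitmap, bitmap_to_intervals


def iv(start, end, chrom="chrA", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def gene(gid, start, end, strand, chrom="chrA", exons=None):
    span = GenomicInterval(chrom, start, end, strand)
    exons = tuple(exons) if exons else (span,)
    return GeneAnnotation(gid, (Transcript(f"{gid}.t", span, exons),))


def peak(start, end, chrom="chrA"):
    return PeakCall(
        interval=GenomicInterval(chrom, start, end), fold_enrichment=5, neg_log10_q=10
    )


class TestUnionEnhancerStates:
    def test_union_across_tracks(self):
        a = SegmentationTrack("A", [(iv(100, 200), 4)])
        b = SegmentationTrack("B", [(iv(150, 300), 6)])
        assert union_enhancer_states([a, b]) == [iv(100, 300)]

    def test_non_enhancer_states_ignored(self):
        a = SegmentationTrack("A", [(iv(0, 500), 1), (iv(500, 900), 2)])
        assert union_enhancer_states([a]) == []

    def test_unknown_state_warns_but_proceeds(self, caplog):
        a = SegmentationTrack("A", [(iv(0, 100), 4)])
        with caplog.at_level("WARNING"):
            got = union_enhancer_states([a], enhancer_state_ids={4, 99})
        assert got == [iv(0, 100)]
        assert "99" in caplog.text

    def test_matches_bitmap_oracle_on_random_tracks(self):
        rng = np.random.default_rng(5)
        tracks = []
        for line in range(3):
            pos, segs = 0, []
            while pos < 50_000:
                length = int(rng.integers(200, 2_000))
                segs.append((iv(pos, pos + length), int(rng.integers(1, 9))))
                pos += length
            tracks.append(SegmentationTrack(f"L{line}", segs))
        got = union_enhancer_states(tracks)
        wanted = [
            s[0] for t in tracks for s in t.segments if s[1] in {4, 5, 6, 7}
        ]
        assert got == bitmap_to_intervals(bitmap(wanted))


class TestBlacklist:
    def test_symmetric_window_around_tss(self):
        g = gene("g", 5000, 9000, "+")
        assert build_blacklist([g], flank=1000) == [iv(4000, 6001)]

    def test_minus_strand_tss_is_span_end(self):
        g = gene("g", 5000, 9000, "-")
        assert build_blacklist([g], flank=1000) == [iv(7999, 10000)]

    def test_no_annotations(self):
        assert build_blacklist([], flank=1000) == []

    def test_close_tss_windows_merge(self):
        g1 = gene("g1", 5000, 8000, "+")
        g2 = gene("g2", 5500, 9000, "+")
        assert build_blacklist([g1, g2], flank=1000) == [iv(4000, 6501)]


class TestAnnotationDrop:
    def test_sense_antisense_pair_removes_region(self):
        genes = [gene("g1", 0, 1000, "+"), gene("g2", 500, 1500, "-")]
        assert drop_bidirectionally_annotated([iv(400, 600)], genes) == []

    def test_single_strand_keeps_region(self):
        genes = [gene("g1", 0, 1000, "+")]
        assert drop_bidirectionally_annotated([iv(400, 600)], genes) == [iv(400, 600)]

    def test_region_overlapping_nothing_kept(self):
        genes = [gene("g1", 0, 100, "+"), gene("g2", 0, 100, "-")]
        assert drop_bidirectionally_annotated([iv(5000, 5600)], genes) == [iv(5000, 5600)]


class TestCofactorRequirement:
    def test_p300_only_removed(self):
        assert require_cofactor_peaks([iv(0, 500)], [peak(100, 200)], []) == []

    def test_both_cofactors_kept(self):
        got = require_cofactor_peaks([iv(0, 500)], [peak(100, 200)], [peak(300, 400)])
        assert len(got) == 1 and got[0].has_p300 and got[0].has_pol2

    def test_abutting_peak_does_not_count(self):
        # peak starts exactly at region end: half-open, no shared base
        assert require_cofactor_peaks([iv(0, 500)], [peak(500, 600)], [peak(0, 10)]) == []


class TestCounting:
    def sample_reads(self):
        return {
            "s1": [
                Read5p("chrA", 1000, "+"),  # exactly at extended start
                Read5p("chrA", 999, "+"),  # 1 bp left of it
                Read5p("chrA", 2500, "-"),
                Read5p("chrA", 3999, "-"),  # last base of extended window
                Read5p("chrA", 4000, "+"),  # just past it
            ]
        }

    def test_boundary_inclusion(self):
        cand = CandidateRegion(interval=iv(2000, 3000), extended_interval=iv(2000, 3000))
        (got,) = count_stranded_reads([cand], self.sample_reads(), flank=1000)
        assert got.counts["s1"] == (1, 2)
        assert got.extended_interval == iv(1000, 4000)

    def test_brute_force_recount_on_random_reads(self):
        rng = np.random.default_rng(11)
        reads = [
            Read5p("chrA", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 20_000, size=2_000)
        ]
        regions = [
            CandidateRegion(interval=iv(s, s + 800), extended_interval=iv(s, s + 800))
            for s in range(0, 18_000, 3_000)
        ]
        got = count_stranded_reads(regions, {"s": reads}, flank=500)
        for cand in got:
            ext = cand.extended_interval
            plus = sum(
                1 for r in reads if r.strand == "+" and ext.start <= r.pos < ext.end
            )
            minus = sum(
                1 for r in reads if r.strand == "-" and ext.start <= r.pos < ext.end
            )
            assert cand.counts["s"] == (plus, minus)

    def test_reads_counted_once_per_overlapping_region(self):
        reads = {"s": [Read5p("chrA", 1500, "+")]}
        regions = [
            CandidateRegion(interval=iv(1000, 2000), extended_interval=iv(1000, 2000)),
            CandidateRegion(interval=iv(1400, 2400), extended_interval=iv(1400, 2400)),
        ]
        got = count_stranded_reads(regions, reads, flank=0)
        assert [c.counts["s"] for c in got] == [(1, 0), (1, 0)]


class TestBidirectionality:
    def make(self, plus, minus):
        c = CandidateRegion(interval=iv(0, 100), extended_interval=iv(0, 100))
        c.counts = {"s1": (plus, minus)}
        return c

    def test_unidirectional_removed(self):
        assert require_bidirectional([self.make(3, 0)]) == []

    def test_one_read_each_strand_kept_at_default(self):
        assert len(require_bidirectional([self.make(1, 1)])) == 1

    def test_higher_threshold(self):
        assert require_bidirectional([self.make(4, 10)], min_reads_per_strand=5) == []


class TestCollapseTranscripts:
    def test_same_strand_overlap_collapses(self):
        g1 = gene("g1", 0, 1000, "+", exons=[iv(0, 200, strand="+"), iv(800, 1000, strand="+")])
        g2 = gene("g2", 500, 1500, "+", exons=[iv(500, 700, strand="+"), iv(1300, 1500, strand="+")])
        got = collapse_transcripts([g1, g2])
        assert len(got) == 1
        assert got[0].gene_id == "g1|g2"

    def test_antisense_pair_stays_separate(self):
        g1 = gene("g1", 0, 1000, "+")
        g2 = gene("g2", 500, 1500, "-")
        assert len(collapse_transcripts([g1, g2])) == 2

    def test_exon_union_matches_bitmap(self):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(20):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(500, 3_000))
            n_ex = int(rng.integers(1, 4))
            exons = []
            for _ in range(n_ex):
                es = int(rng.integers(start, end - 50))
                exons.append(iv(es, min(end, es + int(rng.integers(50, 400))), strand="+"))
            genes.append(gene(f"g{i}", start, end, "+", exons=exons))
        collapsed = collapse_transcripts(genes)
        all_exons = [e for g in collapsed for e in g.transcripts[0].exons]
        wanted = bitmap_to_intervals(
            bitmap([e for g in genes for e in g.transcripts[0].exons])
        )
        assert sorted((e.chrom, e.start, e.end) for e in all_exons) == [
            (w.chrom, w.start, w.end) for w in wanted
        ]


class TestFilterChain:
    def test_blacklist_and_cofactor_order_commute(self, dataset):
        """Both are pure filters, so applying the TSS blacklist before or
        after the cofactor requirement yields the same final region set."""
        from ernaflow.discovery import (
            DEFAULT_ENHANCER_STATES,
            subtract_intervals,
        )

        reads = {s: ReadIndex(dataset.reads_as_records(s)) for s in dataset.reads}
        standard = call_enhancers(
            dataset.tracks,
            dataset.annotations,
            dataset.p300_peaks,
            dataset.pol2_peaks,
            reads,
        )
        # permuted: cofactor requirement first, blacklist second
        regions = union_enhancer_states(dataset.tracks, DEFAULT_ENHANCER_STATES)
        with_cof = [
            c.interval
            for c in require_cofactor_peaks(regions, dataset.p300_peaks, dataset.pol2_peaks)
        ]
        blacklist = build_blacklist(dataset.annotations)
        trimmed = subtract_intervals(with_cof, blacklist)
        trimmed = drop_bidirectionally_annotated(trimmed, dataset.annotations)
        permuted = require_cofactor_peaks(trimmed, dataset.p300_peaks, dataset.pol2_peaks)
        permuted = count_stranded_reads(permuted, reads)
        permuted = require_bidirectional(permuted)
        assert {c.region_id for c in standard} == {c.region_id for c in permuted}
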