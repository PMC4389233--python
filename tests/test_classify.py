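"""p53 peak filtering, BER/FER assignment, the bidirectional midpoint,
drop-off profiles, nearest-gene distances and motif windows/backgrounds."""

import numpy as np
import pytest

from ernaflow.classify import (
    BER,
    FER,
    UnidirectionalRegionError,
    assign_p53_class,
    bidirectional_midpoint,
    dropoff_profile,
    extract_motif_windows,
    filter_tf_peaks,
    nearest_gene_distances,
    select_backgrounds,
)
from ernaflow.discovery import CandidateRegion, ReadIndex
from ernaflow.formats import GeneAnnotation, PeakCall, Read5p, Transcript
from ernaflow.intervals import GenomicInterval


def iv(start, end, chrom="chrA", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def peak(start, end, fold=5.0, q=10.0, chrom="chrA"):
    return PeakCall(
        interval=GenomicInterval(chrom, start, end), fold_enrichment=fold, neg_log10_q=q
    )


def candidate(start, end, ext_start=None, ext_end=None, chrom="chrA"):
    return CandidateRegion(
        interval=iv(start, end, chrom),
        extended_interval=iv(
            start if ext_start is None else ext_start,
            end if ext_end is None else ext_end,
            chrom,
        ),
    )


class TestPeakFilter:
    @pytest.mark.parametrize(
        "fold,q,kept",
        [
            (3.0, 2.0, True),  # equality survives ("lower than" is discarded)
            (2.9, 5.0, False),
            (5.0, 1.9, False),
            (10.0, 10.0, True),
        ],
    )
    def test_threshold_rules(self, fold, q, kept):
        got = filter_tf_peaks([peak(0, 100, fold=fold, q=q)])
        assert (len(got) == 1) == kept

    def test_empty_input(self):
        assert filter_tf_peaks([]) == []


class TestP53Class:
    def test_overlapping_peak_is_ber(self):
        (got,) = assign_p53_class([candidate(1000, 2000)], [peak(1500, 1800)])
        assert got.p53_class == BER

    def test_gap_exactly_1000_is_ber(self):
        (got,) = assign_p53_class([candidate(1000, 2000)], [peak(3000, 3300)])
        assert got.p53_class == BER

    def test_gap_1001_is_fer(self):
        (got,) = assign_p53_class([candidate(1000, 2000)], [peak(3001, 3300)])
        assert got.p53_class == FER

    def test_no_peaks_is_fer(self):
        (got,) = assign_p53_class([candidate(1000, 2000)], [])
        assert got.p53_class == FER


def scan_oracle(ext, plus, minus):
    """Exhaustive scan of the misplaced-read objective over every position."""
    best_p, best = None, None
    for p in range(ext.start, ext.end):
        obj = sum(1 for x in plus if x < p) + sum(1 for x in minus if x >= p)
        if best is None or obj < best:
            best, best_p = obj, p
    return best_p


class TestMidpoint:
    def index(self, plus, minus, chrom="chrA"):
        return ReadIndex(
            [Read5p(chrom, p, "+") for p in plus] + [Read5p(chrom, m, "-") for m in minus]
        )

    def test_separated_strands_tie_break_smallest(self):
        cand = candidate(0, 400)
        got = bidirectional_midpoint(cand, self.index([200, 210], [100, 110]))
        assert got == 111  # any p in (110, 200] is optimal; smallest wins
        assert got == scan_oracle(cand.extended_interval, [200, 210], [100, 110])

    def test_matches_scan_oracle_on_interleaved_reads(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            cand = candidate(0, 300)
            plus = sorted(rng.integers(0, 300, size=rng.integers(1, 12)).tolist())
            minus = sorted(rng.integers(0, 300, size=rng.integers(1, 12)).tolist())
            got = bidirectional_midpoint(cand, self.index(plus, minus))
            assert got == scan_oracle(cand.extended_interval, plus, minus)

    def test_single_read_pair(self):
        cand = candidate(0, 400)
        assert bidirectional_midpoint(cand, self.index([250], [100])) == 101

    def test_unidirectional_region_errors(self):
        with pytest.raises(UnidirectionalRegionError):
            bidirectional_midpoint(candidate(0, 400), self.index([10, 20], []))


class TestDropoff:
    def classified(self, mid, p53_class=BER, start=0, end=10_000):
        from ernaflow.classify import ClassifiedEnhancer

        return ClassifiedEnhancer(
            region=candidate(start, end), p53_class=p53_class, midpoint=mid
        )

    def test_all_reads_in_first_bin(self):
        reads = ReadIndex([Read5p("chrA", 5000 + d, "+") for d in (0, 10, 50)])
        profiles, q75 = dropoff_profile([self.classified(5000)], reads, bin_bp=100, max_bp=1000)
        assert q75.iloc[0] == 100.0

    def test_uniform_density_q75_at_third_bin(self):
        # one read per bin over 4 bins: cumulative hits 0.75 at bin 3's edge
        reads = ReadIndex([Read5p("chrA", 5000 + d, "+") for d in (50, 150, 250, 350)])
        _profiles, q75 = dropoff_profile([self.classified(5000)], reads, bin_bp=100, max_bp=400)
        assert q75.iloc[0] == 300.0

    def test_per_enhancer_density_sums_to_one(self):
        rng = np.random.default_rng(2)
        reads = ReadIndex(
            [Read5p("chrA", 5000 + int(d), "+") for d in rng.exponential(300, 200)]
            + [Read5p("chrA", 4999 - int(d), "-") for d in rng.exponential(300, 200)]
        )
        profiles, _ = dropoff_profile([self.classified(5000)], reads, bin_bp=100, max_bp=2000)
        assert profiles.loc[BER].sum() == pytest.approx(1.0, abs=1e-9)

    def test_both_strands_oriented_downstream(self):
        reads = ReadIndex(
            [Read5p("chrA", 5000, "+"), Read5p("chrA", 4999, "-")]
        )
        profiles, _ = dropoff_profile([self.classified(5000)], reads, bin_bp=100, max_bp=500)
        assert profiles.loc[BER, "bin_100"] == pytest.approx(1.0)

    def test_planted_dropoff_classes_are_ordered(self, dataset, pipeline_result):
        """Bound enhancers are planted with a shorter transcription drop-off
        than free ones, so the median q75 distance must order BER < FER."""
        from ernaflow import classify

        reads = dataset.read_index(
            [s for s, c in dataset.conditions.items() if c == "treated"]
        )
        enhancers = []
        for ce in pipeline_result.classified:
            try:
                mid = bidirectional_midpoint(ce.region, reads)
            except UnidirectionalRegionError:
                continue
            enhancers.append(
                classify.ClassifiedEnhancer(
                    region=ce.region, p53_class=ce.p53_class, midpoint=mid
                )
            )
        _profiles, q75 = dropoff_profile(enhancers, reads)
        by_class = {
            cls: [q75[e.region.region_id] for e in enhancers if e.p53_class == cls]
        for cls in (BER, FER)}
        assert np.median(by_class[BER]) < np.median(by_class[FER])


class TestNearestGenes:
    def gene(self, gid, start, end, strand="+", chrom="chrA"):
        span = GenomicInterval(chrom, start, end, strand)
        return GeneAnnotation(gid, (Transcript(f"{gid}.t", span, (span,)),))

    def classified(self, start, end):
        from ernaflow.classify import ClassifiedEnhancer

        return ClassifiedEnhancer(region=candidate(start, end), p53_class=FER)

    def test_enhancer_inside_gene_distance_zero(self):
        df = nearest_gene_distances(
            [self.classified(1000, 1200)],
            [self.gene("gi", 500, 5000)],
            [self.gene("gn", 50_000, 60_000)],
        )
        assert df["dist_induced_gene"].iloc[0] == 0

    def test_gap_to_nearest_gene(self):
        df = nearest_gene_distances(
            [self.classified(0, 100)],
            [self.gene("gi", 500, 900), self.gene("gi2", 5_000, 9_000)],
            [self.gene("gn", 10_000, 11_000)],
        )
        assert df["dist_induced_gene"].iloc[0] == 400
        assert df["dist_nonregulated_gene"].iloc[0] == 9_900

    def test_mirror_invariance(self):
        size = 100_000
        d1 = nearest_gene_distances(
            [self.classified(1000, 1200)],
            [self.gene("gi", 4000, 6000)],
            [self.gene("gn", 20_000, 30_000)],
        )
        d2 = nearest_gene_distances(
            [self.classified(size - 1200, size - 1000)],
            [self.gene("gi", size - 6000, size - 4000, strand="-")],
            [self.gene("gn", size - 30_000, size - 20_000, strand="-")],
        )
        assert (
            d1["dist_induced_gene"].iloc[0] == d2["dist_induced_gene"].iloc[0]
        )

    def test_overlapping_gene_sets_rejected(self):
        g = self.gene("g", 0, 10)
        with pytest.raises(ValueError):
            nearest_gene_distances([self.classified(0, 5)], [g], [g])


class TestMotifWindows:
    def test_window_centred_on_midpoint(self):
        from ernaflow.classify import ClassifiedEnhancer

        genome = {"chrA": "".join("ACGT"[i % 4] for i in range(10_000))}
        ce = ClassifiedEnhancer(
            region=candidate(4_000, 6_000), p53_class=BER, midpoint=5_000
        )
        ((rid, seq),) = extract_motif_windows([ce], genome, width=200)
        assert len(seq) == 200
        assert seq == genome["chrA"][4_900:5_100]

    def test_truncated_at_chromosome_start(self):
        from ernaflow.classify import ClassifiedEnhancer

        genome = {"chrA": "A" * 500}
        ce = ClassifiedEnhancer(
            region=candidate(0, 200), p53_class=BER, midpoint=40
        )
        ((_, seq),) = extract_motif_windows([ce], genome, width=200)
        assert seq == "A" * 140  # [0, 140) after truncation

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            extract_motif_windows([], {}, width=201)


class TestBackgrounds:
    def test_fdr_floor_both_strands_and_fer_exclusion(self):
        quiet = candidate(0, 500)
        near_quiet = candidate(10_000, 10_500)  # quiet but p53 peak at gap 900
        active = candidate(20_000, 20_500)  # strand FDR below floor
        plus_fdr = {c.region_id: f for c, f in [(quiet, 0.9), (near_quiet, 0.8), (active, 0.74)]}
        minus_fdr = {c.region_id: 0.99 for c in (quiet, near_quiet, active)}
        p53 = [peak(11_400, 11_700)]  # gap 900 from near_quiet
        ber_bg, fer_bg = select_backgrounds(
            [quiet, near_quiet, active], plus_fdr, minus_fdr, p53
        )
        assert {c.region_id for c in ber_bg} == {quiet.region_id, near_quiet.region_id}
        assert {c.region_id for c in fer_bg} == {quiet.region_id}
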