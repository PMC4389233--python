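"""Clone-matrix summaries, the chi-square association, published-table
statistics and the expression anti-correlation."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from ernaflow.methylation import (
    METHYLATED,
    TP53_MUT,
    TP53_WT,
    UNMETHYLATED,
    CloneMatrix,
    ContingencyTable,
    association_summary,
    call_methylated,
    chi_square_2x2,
    expression_methylation_anticorrelation,
    load_clone_matrices,
    methylation_fraction,
    percent,
    tumour_frequency_table,
    write_clone_matrices,
)
from ernaflow.simulate import simulate_methylation_cohort
from oracles import pearson_chi2_rc


class TestCloneFractions:
    def test_all_methylated(self):
        cm = CloneMatrix("s", TP53_WT, np.ones((3, 4)))
        assert methylation_fraction(cm) == 1.0

    def test_half(self):
        m = np.concatenate([np.ones((5, 10)), np.zeros((5, 10))])
        assert methylation_fraction(CloneMatrix("s", TP53_WT, m)) == 0.5

    def test_missing_excluded_from_denominator(self):
        # 3x4 fixture: 5 methylated, 4 unmethylated, 3 missing -> 5/9
        m = np.array(
            [
                [1, 1, np.nan, 0],
                [1, np.nan, 1, 0],
                [np.nan, 1, 0, 0],
            ]
        )
        assert methylation_fraction(CloneMatrix("s", TP53_WT, m)) == pytest.approx(5 / 9)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            methylation_fraction(CloneMatrix("s", TP53_WT, np.full((2, 2), np.nan)))

    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.9, METHYLATED), (0.49, UNMETHYLATED), (0.5, METHYLATED)],
    )
    def test_call_threshold_inclusive(self, fraction, expected):
        assert call_methylated(fraction) == expected


class TestChiSquare:
    def test_cell_line_cohort_table(self):
        # 29/48 methylated in TP53-WT lines vs 30/87 in mutants
        chi2, p = chi_square_2x2(ContingencyTable(29, 30, 19, 57))
        assert f"{p:.3f}" == "0.004"
        assert chi2 == pytest.approx(8.456, abs=0.001)

    def test_proportional_rows_give_zero(self):
        chi2, p = chi_square_2x2(ContingencyTable(10, 20, 30, 60))
        assert chi2 == 0.0
        assert p == 1.0

    def test_diagonal_table_closed_form(self):
        chi2, _ = chi_square_2x2(ContingencyTable(10, 0, 0, 10))
        assert chi2 == pytest.approx(20.0)

    def test_matches_generic_pearson_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 80, size=4)
            table = ContingencyTable(int(a), int(b), int(c), int(d))
            chi2, p = chi_square_2x2(table)
            assert chi2 == pytest.approx(pearson_chi2_rc(table.as_array()), rel=1e-9)
            scipy_chi2, scipy_p, _, _ = chi2_contingency(
                table.as_array(), correction=False
            )
            assert chi2 == pytest.approx(scipy_chi2, rel=1e-9)
            assert p == pytest.approx(scipy_p, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable(0, 0, 5, 5))


class TestAssociationSummary:
    def cohort_calls(self):
        calls = []
        calls += [(METHYLATED, TP53_WT)] * 29 + [(UNMETHYLATED, TP53_WT)] * 19
        calls += [(METHYLATED, TP53_MUT)] * 30 + [(UNMETHYLATED, TP53_MUT)] * 57
        return calls

    def test_cell_line_cohort_percentages(self):
        s = association_summary(self.cohort_calls())
        assert (s.pct_wt, s.pct_mut, s.pct_overall) == (60, 34, 44)
        assert f"{s.p_value:.3f}" == "0.004"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            association_summary([(METHYLATED, TP53_WT)])

    def test_rounding_half_away_from_zero(self):
        assert percent(1, 3) == 33
        assert percent(1, 2) == 50
        assert percent(7, 8) == 88  # 87.5 rounds up

    def test_truncation_convention_available(self):
        assert percent(1, 6, convention="trunc") == 16
        assert percent(1, 6, convention="round") == 17


class TestTumourFrequency:
    def test_published_frequency_rows(self):
        calls = []
        for ttype, n_meth, n in [
            ("Acute lymphocytic leukaemia", 21, 95),
            ("Folicular lymphomas", 1, 10),
            ("Chronic lymphocytic leukaemia", 1, 33),
        ]:
            calls += [(METHYLATED, ttype)] * n_meth
            calls += [(UNMETHYLATED, ttype)] * (n - n_meth)
        df = tumour_frequency_table(calls).set_index("tumour_type")
        assert df.loc["Acute lymphocytic leukaemia", "percent"] == 22
        assert df.loc["Folicular lymphomas", "percent"] == 10
        assert df.loc["Chronic lymphocytic leukaemia", "percent"] == 3
        assert list(df["percent"]) == sorted(df["percent"], reverse=True)

    def test_zero_methylated(self):
        df = tumour_frequency_table([(UNMETHYLATED, "X")] * 5)
        assert df["percent"].iloc[0] == 0


class TestAnticorrelation:
    def test_silencing_signature_is_negative(self):
        expr = [0.0, 0.0, 0.1, 5.0, 6.0, 7.0]
        calls = [METHYLATED] * 3 + [UNMETHYLATED] * 3
        r, p = expression_methylation_anticorrelation(expr, calls)
        assert r == pytest.approx(-1.0)

    def test_identical_groups_statistic_zero(self):
        expr = [1.0] * 6
        calls = [METHYLATED] * 3 + [UNMETHYLATED] * 3
        r, p = expression_methylation_anticorrelation(expr, calls)
        assert r == 0.0 and p == 1.0

    def test_permuted_labels_p_uniform(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=24)
        ps = []
        for _ in range(200):
            labels = [METHYLATED] * 12 + [UNMETHYLATED] * 12
            rng.shuffle(labels)
            ps.append(expression_methylation_anticorrelation(expr, labels)[1])
        # permutation null: p-values roughly uniform (coarse KS gate)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestCohortSimulation:
    def test_clone_count_convention(self):
        cohort = simulate_methylation_cohort(n_wt=3, n_mut=3, seed=0)
        assert all(cm.matrix.shape[0] == 10 for cm in cohort)

    def test_reproducible_matrices(self):
        a = simulate_methylation_cohort(n_wt=5, n_mut=5, seed=42)
        b = simulate_methylation_cohort(n_wt=5, n_mut=5, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.matrix, y.matrix)

    def test_null_association_p_approximately_uniform(self):
        """With equal methylation propensity in both TP53 groups the
        chi-square p-value is approximately uniform over repetitions (the
        statistic is discrete over integer tables, so the check is on
        calibrated tail fractions rather than an exact KS)."""
        ps = []
        for seed in range(100):
            cohort = simulate_methylation_cohort(
                n_wt=40, n_mut=40, p_meth_wt=0.5, p_meth_mut=0.5, seed=seed
            )
            calls = [
                (call_methylated(methylation_fraction(cm)), cm.tp53_status)
                for cm in cohort
            ]
            ps.append(association_summary(calls).p_value)
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.15
        assert 0.25 < (ps < 0.5).mean() < 0.75

    def test_power_at_published_group_rates(self):
        """At the study's group sizes (48 WT, 87 mutant) and methylation
        rates (0.60 vs 0.34) the test rejects at alpha 0.05 in >=70% of
        repetitions."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cohort = simulate_methylation_cohort(seed=seed)
            calls = [
                (call_methylated(methylation_fraction(cm)), cm.tp53_status)
                for cm in cohort
            ]
            if association_summary(calls).p_value < 0.05:
                rejections += 1
        assert rejections / n_seeds >= 0.70

    def test_roundtrip_through_tsv(self, tmp_path):
        cohort = simulate_methylation_cohort(
            n_wt=3, n_mut=2, seed=7, tumour_types=["ALL", "AML"]
        )
        clones, meta = tmp_path / "clones.tsv", tmp_path / "meta.tsv"
        write_clone_matrices(clones, meta, cohort)
        back = {cm.sample_id: cm for cm in load_clone_matrices(clones, meta)}
        for cm in cohort:
            got = back[cm.sample_id]
            np.testing.assert_array_equal(got.matrix, cm.matrix)
            assert got.tp53_status == cm.tp53_status
            assert got.tumour_type == cm.tumour_type
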