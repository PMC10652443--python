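"""Tests for cohort statistics: frequency tables, proportion/mean tests, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelprofiler import (
    PatientRecord,
    ValidationError,
    adjust_pvalues,
    biomarker_site_comparison,
    categorical_breakdown,
    compare_gene_frequencies,
    compare_means,
    compare_proportions,
    frequency_table,
    mean_sem,
)
from oracles import (
    bh_stepup_bruteforce,
    chi2_2x2_closed_form,
    fisher_twosided_enumeration,
)


class TestFrequencyTable:
    def test_printed_cohort_percentages(self, table1_cohort):
        freq = frequency_table(table1_cohort, ["KRAS", "TP53"]).set_index("gene")
        assert freq.loc["KRAS", "count"] == 152
        assert freq.loc["KRAS", "percentage"] == round(100 * 152 / 298, 2)
        assert freq.loc["TP53", "count"] == 158
        assert freq.loc["TP53", "percentage"] == round(100 * 158 / 298, 2)

    def test_absent_gene_reports_zero(self, table1_cohort):
        freq = frequency_table(table1_cohort, ["BRAF"])
        assert freq.iloc[0]["count"] == 0
        assert freq.iloc[0]["percentage"] == 0.00

    def test_invariant_under_reordering(self, table1_cohort):
        shuffled = list(reversed(table1_cohort))
        a = frequency_table(table1_cohort, ["KRAS"])
        b = frequency_table(shuffled, ["KRAS"])
        assert a.equals(b)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            frequency_table([], ["KRAS"])


class TestCategoricalBreakdown:
    def test_sex_split(self, table1_cohort):
        out = categorical_breakdown(table1_cohort, "sex").set_index("level")
        assert out.loc["male", "count"] == 184
        assert out.loc["male", "percentage"] == 61.74
        assert out.loc["female", "percentage"] == 38.26

    def test_site_split(self, table1_cohort):
        out = categorical_breakdown(table1_cohort, "site").set_index("level")
        assert out.loc["duodenum", "percentage"] == 89.93
        ji = out.loc["jejunum", "count"] + out.loc["ileum", "count"]
        assert round(100 * ji / 298, 2) == 10.07

    def test_age_dichotomy(self, table1_cohort):
        out = categorical_breakdown(table1_cohort, "age_ge_60").set_index("level")
        assert out.loc["age>=60", "count"] == 149
        assert out.loc["age>=60", "percentage"] == 50.00

    def test_single_patient(self):
        p = PatientRecord("X", "female", 70.0, "ileum")
        out = categorical_breakdown([p], "sex")
        assert list(out["percentage"]) == [100.00]

    def test_unknown_field_rejected(self, table1_cohort):
        with pytest.raises(ValidationError):
            categorical_breakdown(table1_cohort, "height")


class TestCompareProportions:
    def test_identical_balanced_proportions(self):
        test, stat, p = compare_proportions(5, 10, 5, 10)
        assert p == pytest.approx(1.0)
        assert stat == pytest.approx(0.0) or test == "fisher"

    def test_chi_square_matches_closed_form(self):
        test, stat, p = compare_proportions(50, 100, 30, 100)
        assert test == "chi-square"
        assert stat == pytest.approx(chi2_2x2_closed_form(50, 50, 30, 70))
        assert stat == pytest.approx(25 / 3)

    def test_small_expected_cells_force_fisher(self):
        test, _, p = compare_proportions(1, 5, 4, 5)
        assert test == "fisher"
        assert p == pytest.approx(
            fisher_twosided_enumeration(1, 4, 4, 1), rel=1e-9
        )

    def test_symmetric_in_group_order(self):
        t1, _, p1 = compare_proportions(7, 40, 19, 31)
        t2, _, p2 = compare_proportions(19, 31, 7, 40)
        assert t1 == t2 and p1 == pytest.approx(p2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            compare_proportions(0, 0, 3, 10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.integers(0, 15), ta=st.integers(1, 15),
        b=st.integers(0, 15), tb=st.integers(1, 15),
    )
    def test_fisher_path_matches_enumeration(self, a, ta, b, tb):
        a, b = min(a, ta), min(b, tb)
        test, _, p = compare_proportions(a, ta, b, tb)
        if test == "fisher":
            assert p == pytest.approx(
                fisher_twosided_enumeration(a, ta - a, b, tb - b), rel=1e-9
            )


class TestCompareMeans:
    def test_identical_samples(self):
        out = compare_means([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert out["p_value"] == pytest.approx(1.0)
        assert out["statistic"] == pytest.approx(0.0)

    def test_mean_sem_closed_form(self):
        m, s = mean_sem([1.0, 2.0, 3.0])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(1.0 / np.sqrt(3.0))

    def test_three_groups_use_anova(self):
        rng = np.random.default_rng(3)
        out = compare_means([rng.normal(size=10) for _ in range(3)])
        assert out["test_used"] == "anova"

    def test_student_flag(self):
        rng = np.random.default_rng(4)
        out = compare_means(
            [rng.normal(size=10), rng.normal(size=10)], welch=False
        )
        assert out["test_used"] == "student-t"

    def test_short_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_means([[1.0], [1.0, 2.0]])


class TestAdjustPvalues:
    def test_hand_applied_stepup(self):
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_and_empty(self):
        assert adjust_pvalues([1.0]) == [1.0]
        assert adjust_pvalues([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_bruteforce_and_never_below_input(self, ps):
        adj = adjust_pvalues(ps)
        assert adj == pytest.approx(bh_stepup_bruteforce(ps))
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))


class TestCohortComparisons:
    def test_gene_frequency_contrast_counts(self, table1_cohort):
        out = compare_gene_frequencies(
            ["KRAS"], {"KRAS": 152}, 298, {"KRAS": 80}, 200,
            label_a="this-cohort", label_b="external",
        )
        c = out[0]
        assert c.freq_a == pytest.approx(152 / 298)
        assert c.freq_b == pytest.approx(0.4)
        assert c.p_adjusted >= c.p_value

    def test_site_biomarker_power_on_known_effect(self):
        """With MSI-H priors 0.05 (duodenum) vs 0.30 (jejunum/ileum) at n=500
        the comparison must detect the enrichment at alpha = 0.05."""
        rng = np.random.default_rng(21)
        cohort = []
        for i in range(500):
            site = "duodenum" if i < 400 else ("jejunum" if i < 450 else "ileum")
            prob = 0.05 if site == "duodenum" else 0.30
            msih = rng.random() < prob
            cohort.append(
                PatientRecord(
                    patient_id=f"S{i}", sex="male", age=60.0, site=site,
                    msi_class="MSI-H" if msih else "MSS",
                    tmb_per_mb=float(rng.gamma(4, 6 if msih else 1)),
                    pdl1_tps=float(rng.uniform(0, 100)),
                )
            )
        report = biomarker_site_comparison(cohort, merge_jejunum_ileum=True)
        msi = report["msi_h"]["pairwise"]["duodenum vs jejunum/ileum"]
        assert msi["p_value"] < 0.05
        d = report["sites"]["duodenum"]["msi_h_proportion"]
        ji = report["sites"]["jejunum/ileum"]["msi_h_proportion"]
        assert ji > d
        assert report["tmb"]["p_value"] < 0.05

    def test_single_site_cohort_rejected(self):
        cohort = [
            PatientRecord(f"S{i}", "male", 60.0, "duodenum") for i in range(5)
        ]
        with pytest.raises(ValidationError):
            biomarker_site_comparison(cohort)

    def test_empty_site_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        cohort = [
            PatientRecord(
                f"S{i}", "male", 60.0, "duodenum" if i < 10 else "jejunum",
                tmb_per_mb=float(rng.gamma(4, 1)),
            )
            for i in range(20)
        ]
        with pytest.warns(UserWarning, match="ileum"):
            report = biomarker_site_comparison(cohort)
        assert report["dropped_sites"] == ["ileum"]
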