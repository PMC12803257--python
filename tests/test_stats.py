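"""Regenerative Index arithmetic and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regenquant as rq
from regenquant.stats import RI, round_half_away


class TestComputeRI:
    @pytest.mark.parametrize(
        "n_emhc, n_igg, expected",
        [
            (105, 21, 5.0),
            (492, 48, 10.3),  # 10.25 must round up, away from zero
            (205.5, 29, 7.1),
            (87.5, 40.5, 2.2),
            (3, 10, 0.3),
            (0, 5, 0.0),
        ],
    )
    def test_defined_values(self, n_emhc, n_igg, expected):
        ri = rq.compute_ri(n_emhc, n_igg)
        assert ri.defined
        assert ri.rounded == expected

    def test_zero_over_zero_is_undefined(self):
        ri = rq.compute_ri(0, 0)
        assert ri.status == "undefined"
        assert ri.value is None
        assert str(ri) == "undefined"

    def test_regeneration_without_necrosis_is_flagged_infinite(self):
        ri = rq.compute_ri(7, 0)
        assert ri.status == "infinite"
        assert ri.value is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rq.compute_ri(-1, 5)
        with pytest.raises(ValueError):
            rq.compute_ri(5, -1)

    @settings(max_examples=100, derandomize=True)
    @given(
        n_emhc=st.floats(0, 1e4), n_igg=st.floats(0.01, 1e4),
        scale=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, n_emhc, n_igg, scale):
        """RI is a ratio: rescaling both counts (e.g. a bigger section
        with the same pathology) leaves it unchanged."""
        a = rq.compute_ri(n_emhc, n_igg).value
        b = rq.compute_ri(n_emhc * scale, n_igg * scale).value
        assert a == pytest.approx(b, rel=1e-9)


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(10.25, 1, 10.3), (2.15, 1, 2.2), (-2.15, 1, -2.2), (1.234, 2, 1.23)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestSummarizeSample:
    def test_single_replicate_percentages(self):
        s = rq.summarize_sample((48, 492, 2747), "DMD 18", 7)
        assert round_half_away(s.pct_igg, 2) == 1.75
        assert round_half_away(s.pct_emhc, 2) == 17.91
        assert s.ri.rounded == 10.3

    def test_replicates_average_to_fractional_counts(self):
        s = rq.summarize_sample([(29, 205, 1484), (29, 206, 1484)], "x", 7)
        assert s.n_emhc == 205.5

    def test_age_group_boundary(self):
        assert rq.summarize_sample((1, 1, 10), "a", 8).group == "7-8"
        assert rq.summarize_sample((1, 1, 10), "b", 9).group == "9-11"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            rq.summarize_sample((0, 0, 0), "x", 8)


class TestRegression:
    def test_perfect_linear_fit(self):
        ages = [7, 8, 9, 10, 11]
        cohort = [
            rq.summarize_sample((10, 10 * (2 * a + 1), 1000), f"s{a}", a)
            for a in ages
        ]
        reg = rq.regress_vs_age(cohort, "ri", use_rounded_ri=False)
        assert reg.slope == pytest.approx(2.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        cohort = [rq.summarize_sample((5, 10, 100), f"s{i}", 9) for i in range(4)]
        with pytest.raises(ValueError, match="ages identical"):
            rq.regress_vs_age(cohort, "ri")

    def test_too_few_samples_rejected(self):
        cohort = [rq.summarize_sample((5, 10, 100), "a", 7),
                  rq.summarize_sample((5, 10, 100), "b", 9)]
        with pytest.raises(ValueError, match="at least 3"):
            rq.regress_vs_age(cohort, "ri")

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-5, 5))
    def test_r_squared_affine_invariant(self, scale, shift):
        """R² is unchanged by affine rescaling of the response."""
        rng = np.random.default_rng(0)
        ages = np.array([7, 8, 8, 9, 10, 11], float)
        y = 20 - 1.5 * ages + rng.normal(0, 1, len(ages))
        import statsmodels.api as sm

        base = sm.OLS(y, sm.add_constant(ages)).fit().rsquared
        scaled = sm.OLS(scale * y + shift, sm.add_constant(ages)).fit().rsquared
        assert scaled == pytest.approx(base, rel=1e-8)

    def test_controls_excluded_by_default(self, reference_summaries):
        reg = rq.regress_vs_age(reference_summaries, "ri")
        assert reg.n == 10  # DMD samples only


class TestWelch:
    def test_identical_groups(self):
        cmp = rq.welch_ttest([1, 2, 3], [1, 2, 3])
        assert cmp.t_stat == 0
        assert cmp.p == pytest.approx(1.0)

    def test_well_separated_groups(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        assert rq.welch_ttest(a, b).p < 0.01

    def test_matches_independent_implementation(self):
        """Cross-check the Welch statistic/df against statsmodels."""
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        ours = rq.welch_ttest(a, b)
        t, p, df = sm_ttest(a, b, usevar="unequal")
        assert ours.t_stat == pytest.approx(t)
        assert ours.p == pytest.approx(p)
        assert ours.df == pytest.approx(df)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            rq.welch_ttest([1.0], [1, 2, 3])


class TestCohortReport:
    def test_reference_cohort_row_count(self, reference_summaries):
        report = rq.build_cohort_report(reference_summaries)
        assert len(report.table) == 13
        assert (report.table.status == "DMD").sum() == 10

    def test_single_sample_marks_stats_not_computable(self):
        report = rq.build_cohort_report(
            [rq.summarize_sample((5, 10, 100), "only", 9)]
        )
        assert len(report.table) == 1
        assert all(v is None for v in report.regressions.values())
        assert all(v is None for v in report.comparisons.values())

    def test_report_write_is_deterministic(self, reference_summaries, tmp_path):
        report = rq.build_cohort_report(reference_summaries)
        report.write(tmp_path / "a")
        report.write(tmp_path / "b")
        for name in ("cohort_table.csv", "cohort_stats.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
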