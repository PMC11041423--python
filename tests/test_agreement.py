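"""Bland-Altman, one-way ANOVA, RMSE/correlation and box summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhbreath import (
    anova_from_summary,
    bland_altman,
    box_summary,
    one_way_anova,
    rmse_and_correlation,
)


class TestBlandAltman:
    def test_identical_series(self):
        rep = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.bias == 0.0
        assert rep.loa_lower == rep.loa_upper == 0.0
        assert rep.rmse == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0]) + 0.5
        rep = bland_altman(a, [1.0, 2.0, 3.0])
        assert rep.bias == pytest.approx(0.5)
        assert rep.loa_lower == pytest.approx(0.5)
        assert rep.loa_upper == pytest.approx(0.5)

    def test_unit_differences_hand_case(self):
        """Differences {-1, 0, 1}: SD = 1, so LoA = -/+1.96 around bias 0."""
        rep = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert rep.bias == pytest.approx(0.0)
        assert rep.loa_lower == pytest.approx(-1.96)
        assert rep.loa_upper == pytest.approx(1.96)

    def test_loa_symmetry_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(10, 1, 50), rng.normal(10, 1, 50)
        rep = bland_altman(a, b)
        assert rep.loa_upper - rep.bias == pytest.approx(rep.bias - rep.loa_lower)
        assert rep.loa_upper - rep.bias == pytest.approx(1.96 * np.std(rep.diffs, ddof=1))

    def test_percent_mode(self):
        rep = bland_altman([11.0, 22.0], [9.0, 18.0], mode="percent")
        np.testing.assert_allclose(rep.diffs, [20.0, 20.0])
        assert rep.bias == pytest.approx(20.0)

    def test_percent_mode_zero_pair_mean_names_pair(self):
        with pytest.raises(ValueError, match="pair index 1"):
            bland_altman([1.0, 1.0], [2.0, -1.0], mode="percent")

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            bland_altman([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman([1.0], [1.0])

    def test_per_subject_normalisation_removes_scale(self):
        """Two subjects at different levels but identical relative error
        produce the same normalised differences."""
        a = np.array([1.1, 1.1, 11.0, 11.0])
        b = np.array([1.0, 1.0, 10.0, 10.0])
        rep = bland_altman(a, b, normalize="per_subject_mean", subjects=[0, 0, 1, 1])
        assert np.ptp(rep.diffs) == pytest.approx(0.0, abs=1e-12)

    def test_mixed_limits_bracket_bias(self):
        rng = np.random.default_rng(5)
        subjects = np.repeat(np.arange(6), 20)
        offsets = rng.normal(0, 0.5, 6)[subjects]
        diffs_a = 10 + offsets + rng.normal(0, 0.2, len(subjects))
        rep = bland_altman(diffs_a, np.full(len(subjects), 10.0),
                           subjects=subjects, loa_method="mixed")
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        # between-subject spread must widen the limits beyond the residual SD
        assert rep.loa_upper - rep.loa_lower > 4 * 0.2

    def test_loa_cover_at_least_93_percent_of_differences(self):
        """Monte-Carlo coverage of the normal-theory limits."""
        rng = np.random.default_rng(11)
        a = rng.normal(50, 5, 2000)
        b = a + rng.normal(0.2, 1.0, 2000)
        rep = bland_altman(a, b)
        inside = np.mean((rep.diffs >= rep.loa_lower) & (rep.diffs <= rep.loa_upper))
        assert inside >= 0.93


class TestOneWayAnova:
    def test_identical_groups(self):
        tab = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert tab.ss_between == pytest.approx(0.0)
        assert tab.f == 0.0
        assert tab.p == 1.0

    def test_hand_computed_decomposition(self):
        """Groups {0,1} and {2,3}: SSb=4, SSw=1, F=8, P=F_sf(8;1,2)~=0.106."""
        tab = one_way_anova([[0.0, 1.0], [2.0, 3.0]])
        assert tab.ss_between == pytest.approx(4.0)
        assert tab.ss_within == pytest.approx(1.0)
        assert tab.f == pytest.approx(8.0)
        assert tab.p == pytest.approx(0.1056, abs=5e-4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i * 0.3, 1.0, 15 + i) for i in range(3)]
        tab = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert tab.f == pytest.approx(ref.statistic, rel=1e-10)
        assert tab.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        tab = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert tab.f == pytest.approx(t.statistic**2, rel=1e-10)
        assert tab.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_zero_within_variance_flagged_degenerate(self):
        tab = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert tab.degenerate
        assert tab.p == 0.0

    def test_all_identical_values(self):
        tab = one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert tab.f == 0.0 and tab.p == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError, match="at least one value"):
            one_way_anova([[1.0], []])

    @given(
        st.lists(
            st.lists(st.floats(-100, 100), min_size=2, max_size=8),
            min_size=2,
            max_size=4,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_sum_of_squares_decomposition_exact(self, groups):
        """SS_total computed directly equals SS_between + SS_within."""
        flat = np.concatenate([np.asarray(g) for g in groups])
        tab = one_way_anova(groups)
        ss_total = float(np.sum((flat - flat.mean()) ** 2))
        assert tab.ss_total == pytest.approx(ss_total, abs=1e-9 + 1e-9 * abs(ss_total))


class TestAnovaFromSummary:
    def test_published_respiratory_rate_row(self):
        """SSb=0.002 (df 1), SSw=39.09 (df 346) reproduce MSw 0.11, P .89."""
        tab = anova_from_summary(0.002, 1, 39.09, 346)
        assert round(tab.ms_within, 2) == 0.11
        assert round(tab.p, 2) == 0.89

    def test_zero_between_is_null(self):
        tab = anova_from_summary(0.0, 1, 10.0, 20)
        assert tab.f == 0.0 and tab.p == 1.0

    def test_self_consistency_with_full_anova(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 10), rng.normal(0.3, 1, 12)]
        full = one_way_anova(groups)
        rebuilt = anova_from_summary(
            full.ss_between, full.df_between, full.ss_within, full.df_within
        )
        assert rebuilt.f == pytest.approx(full.f, abs=1e-12)
        assert rebuilt.p == pytest.approx(full.p, abs=1e-12)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError, match="df_within"):
            anova_from_summary(1.0, 1, 1.0, 0)

    def test_summary_renders_p_to_two_decimals(self):
        text = anova_from_summary(0.002, 1, 39.09, 346).summary()
        assert "0.89" in text


class TestRmseCorrelation:
    def test_identical(self):
        rmse, r = rmse_and_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r == pytest.approx(1.0)

    def test_hand_case(self):
        rmse, _ = rmse_and_correlation([1.0, 2.0, 3.0], [2.0, 2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_perfect_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0])
        _, r = rmse_and_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_constant_input_warns_and_keeps_rmse(self):
        with pytest.warns(UserWarning, match="constant"):
            rmse, r = rmse_and_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert rmse == pytest.approx(np.sqrt(5.0 / 3.0))
        assert np.isnan(r)


class TestBoxSummary:
    def test_five_point_hand_case(self):
        b = box_summary([1, 2, 3, 4, 5])
        assert (b.median, b.q1, b.q3, b.iqr) == (3.0, 2.0, 4.0, 2.0)
        assert len(b.outliers) == 0
        assert b.whisker_low == 1.0 and b.whisker_high == 5.0

    def test_single_value(self):
        b = box_summary([7.5])
        assert b.median == b.q1 == b.q3 == b.whisker_low == b.whisker_high == 7.5

    def test_extreme_point_flagged_outlier(self):
        """With {1,2,3,100}, the 1.5*IQR fence is 65.5 < 100."""
        b = box_summary([1, 2, 3, 100])
        np.testing.assert_array_equal(b.outliers, [100.0])
        assert b.whisker_high == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            box_summary([])

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(1)
        b = box_summary(rng.normal(size=101))
        assert b.q1 <= b.median <= b.q3
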