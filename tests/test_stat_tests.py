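"""Normality gate, one/two-sample tests, Kruskal-Wallis, Holm correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tmaze.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from tmaze.stat_tests import (
    holm_adjust,
    kruskal_wallis,
    normality_gate,
    one_sample_location_test,
    two_sample_test,
)


class TestNormalityGate:
    def test_discrete_two_point_sample_routes_nonparametric(self, rng):
        values = rng.integers(0, 2, size=30).astype(float)
        assert normality_gate(values) == "nonparametric"

    def test_gaussian_sample_usually_routes_parametric(self):
        hits = sum(
            normality_gate(np.random.default_rng(seed).normal(size=100)) == "parametric"
            for seed in range(20)
        )
        assert hits >= 15  # W-test holds its level, so most draws pass

    def test_constant_vector_warns_and_routes_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate([0.5] * 10) == "nonparametric"

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestOneSampleTest:
    def test_symmetric_values_give_t_zero_p_one(self):
        result = one_sample_location_test([0.4, 0.6, 0.3, 0.7], 0.5, method="t")
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 3

    def test_wilcoxon_reports_positive_rank_sum_V(self):
        # five equal positive deviations: tied ranks average to 3, V = 15
        result = one_sample_location_test([0.6] * 5, 0.5, method="wilcoxon")
        assert result.statistic == 15.0
        assert result.test_name == "wilcoxon_signed_rank"

    def test_pratt_zero_handling_keeps_zeros_in_ranking(self):
        # differences {0, +0.2, +0.2, -0.1}: |d| ranks -> 0:1, 0.1:2, 0.2:(3.5, 3.5)
        result = one_sample_location_test([0.5, 0.7, 0.7, 0.4], 0.5, method="wilcoxon")
        assert result.statistic == pytest.approx(7.0)

    def test_matches_reference_t_implementation(self, rng):
        for _ in range(20):
            x = rng.normal(0.55, 0.1, size=rng.integers(5, 40))
            ours = one_sample_location_test(x, 0.5, method="t")
            ref = stats.ttest_1samp(x, 0.5)
            assert ours.statistic == pytest.approx(float(ref.statistic), abs=1e-10)
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_all_values_at_null_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_sample_location_test([0.5, 0.5, 0.5], 0.5, method="wilcoxon")

    def test_auto_routes_by_gate(self, rng):
        heavy_discrete = rng.integers(0, 2, size=30).astype(float)
        heavy_discrete[0] = 0.4  # avoid fully constant halves
        result = one_sample_location_test(heavy_discrete, 0.5, method="auto")
        assert result.test_name == "wilcoxon_signed_rank"


class TestTwoSampleTest:
    def test_identical_samples_give_p_one(self):
        x = [0.4, 0.5, 0.6, 0.7]
        result = two_sample_test(x, list(x), method="t")
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 6  # pooled df: n_a + n_b - 2

    def test_constant_shift_detected_at_large_n(self, rng):
        a = rng.normal(0.5, 0.05, size=200)
        result = two_sample_test(a + 0.1, a, method="t")
        assert result.p_value < 1e-10
        assert result.statistic > 0

    def test_welch_option_reports_welch_df(self, rng):
        a = rng.normal(0, 1, size=10)
        b = rng.normal(0, 5, size=30)
        result = two_sample_test(a, b, method="t", equal_var=False)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert result.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)
        assert result.df != len(a) + len(b) - 2

    def test_matches_reference_mannwhitney(self, rng):
        a = rng.normal(0.5, 0.1, size=15)
        b = rng.normal(0.6, 0.1, size=20)
        ours = two_sample_test(a, b, method="mannwhitney")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert ours.statistic == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_identical_constants_degenerate(self):
        with pytest.raises(DegenerateDataError):
            two_sample_test([0.5, 0.5], [0.5, 0.5], method="t")


class TestKruskalWallis:
    def test_hand_ranked_oracle(self):
        """{1,2,3} vs {4,5,6}: ranks 1..6, H = 12/(6*7)*(6^2/3 + 15^2/3) - 21."""
        expected = 12.0 / 42.0 * (36.0 / 3.0 + 225.0 / 3.0) - 3.0 * 7.0
        result = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert result.statistic == pytest.approx(expected, abs=1e-12)
        assert result.df == 1

    def test_complete_ties_give_zero(self):
        result = kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_reference_implementation(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.2, 1.0, size=12) for i in range(4)}
        ours = kruskal_wallis(groups)
        ref_h, ref_p = stats.kruskal(*groups.values())
        assert ours.statistic == pytest.approx(float(ref_h), abs=1e-10)
        assert ours.p_value == pytest.approx(float(ref_p), abs=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(InsufficientDataError):
            kruskal_wallis({"a": [1, 2, 3]})


class TestHolmAdjust:
    def test_single_p_is_identity(self):
        assert holm_adjust([0.03]) == [0.03]

    def test_two_value_step_down(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_manual_step_down(self, rng):
        """Independent oracle: the textbook step-down loop with monotone max."""
        p = rng.uniform(size=12)
        ours = holm_adjust(list(p))
        order = np.argsort(p)
        m = len(p)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adjusted[idx] = min(1.0, running)
        assert ours == pytest.approx(adjusted, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_dominates_raw_dominated_by_bonferroni(self, pvals):
        adjusted = holm_adjust(pvals)
        bonf = holm_adjust(pvals, method="bonferroni")
        m = len(pvals)
        for raw, adj, b in zip(pvals, adjusted, bonf):
            assert adj >= raw - 1e-15
            assert adj <= b + 1e-15
            assert b == pytest.approx(min(1.0, m * raw), abs=1e-12)
            assert adj <= 1.0 + 1e-15

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.2])


def test_type_one_error_calibration_small_battery(rng):
    """One-sample auto test holds its level on null proportion-like data."""
    rejections = 0
    n_reps = 400
    for _ in range(n_reps):
        values = rng.binomial(250, 0.5, size=29) / 250 - rng.binomial(250, 0.5, size=29) / 250
        rejections += one_sample_location_test(values, 0.0, method="auto").p_value < 0.05
    rate = rejections / n_reps
    assert 0.02 <= rate <= 0.09
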