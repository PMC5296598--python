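"""Binomial MLE, likelihood curves, dispersion, χ² bias and OLS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attmut.errors import FitError, ParameterError
from attmut.spectrum import (
    RoundCounts,
    binom_log_likelihood,
    dispersion_test,
    freq_from_ratio,
    mle_transition_freq,
    ols_ratio_vs_load,
    ratio_from_freq,
    transition_bias_chisq,
)


class TestBinomLogLikelihood:
    def test_single_point_half(self):
        assert binom_log_likelihood(0.5, [(1, 2)]) == pytest.approx(math.log(0.5))

    def test_impossible_datum_is_minus_infinity(self):
        assert binom_log_likelihood(1.0, [(3, 5)]) == -math.inf
        assert binom_log_likelihood(0.0, [(1, 5)]) == -math.inf

    def test_boundary_certain_data_is_zero(self):
        assert binom_log_likelihood(1.0, [(5, 5)]) == 0.0
        assert binom_log_likelihood(0.0, [(0, 5)]) == 0.0

    def test_matches_termwise_product(self):
        data = [(9, 10), (8, 10)]
        p = 0.9
        expected = sum(
            math.log(math.comb(n, k) * p**k * (1 - p) ** (n - k)) for k, n in data
        )
        assert binom_log_likelihood(p, data) == pytest.approx(expected, rel=1e-12)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            binom_log_likelihood(1.5, [(1, 2)])


class TestMleTransitionFreq:
    @pytest.mark.parametrize(
        "data,expected",
        [([(3, 4)], 0.75), ([(9, 10), (8, 10)], 0.85), ([(0, 5)], 0.0)],
    )
    def test_pooled_closed_form(self, data, expected):
        p_hat, _ = mle_transition_freq(data)
        assert p_hat == pytest.approx(expected)

    def test_matches_grid_search_oracle(self):
        data = [(9, 10), (8, 10), (17, 20)]
        p_hat, _ = mle_transition_freq(data)
        grid = np.arange(0, 1 + 1e-9, 1e-4)
        ll = [binom_log_likelihood(p, data) for p in grid]
        assert abs(p_hat - grid[int(np.argmax(ll))]) <= 1e-4

    def test_curve_normalised_with_peak_at_mle(self):
        p_hat, curve = mle_transition_freq([(7, 10), (8, 9)])
        assert curve.likelihood.max() == pytest.approx(1.0)
        at_hat = curve.likelihood[np.argmin(np.abs(curve.p_grid - p_hat))]
        assert at_hat == pytest.approx(1.0)
        assert (curve.likelihood >= 0).all()

    def test_all_zero_n_is_error(self):
        with pytest.raises(FitError):
            mle_transition_freq([(0, 0), (0, 0)])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=12))
    def test_partition_invariance(self, raw):
        # only the pooled Σk/Σn matters, not how counts are split into rounds
        data = [(min(a, b), max(a, b)) for a, b in raw]
        if sum(n for _, n in data) == 0:
            return
        k, n = sum(k for k, _ in data), sum(n for _, n in data)
        p_split, _ = mle_transition_freq(data)
        p_pooled, _ = mle_transition_freq([(k, n)])
        assert p_split == pytest.approx(p_pooled, abs=1e-12)


class TestRatioFreqConversion:
    def test_symmetry_point(self):
        assert ratio_from_freq(0.5) == pytest.approx(1.0)

    def test_study_ratio_implies_96_percent_transitions(self):
        p = freq_from_ratio(22.6)
        assert round(100 * p) == 96

    def test_certain_transition_maps_to_infinity(self):
        assert ratio_from_freq(1.0) == math.inf
        assert freq_from_ratio(math.inf) == 1.0

    def test_negative_ratio_rejected(self):
        with pytest.raises(ParameterError):
            freq_from_ratio(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_round_trip(self, p):
        assert freq_from_ratio(ratio_from_freq(p)) == pytest.approx(p, abs=1e-12)


class TestDispersion:
    def test_constant_counts_have_zero_index(self):
        res = dispersion_test([5, 5, 5, 5], n_boot=1000, seed=0)
        assert res.variance == 0.0 and res.index == 0.0

    def test_burst_counts_hand_arithmetic(self):
        res = dispersion_test([0, 0, 0, 100], n_boot=1000, seed=0)
        assert res.mean == pytest.approx(25.0)
        assert res.variance == pytest.approx(2500.0)
        assert res.index == pytest.approx(100.0)
        assert res.p_value < 0.01

    def test_all_zero_counts(self):
        res = dispersion_test([0, 0, 0], n_boot=1000, seed=0)
        assert res.index == 0.0 and res.p_value == 1.0

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            dispersion_test([5], n_boot=1000)
        with pytest.raises(ParameterError):
            dispersion_test([5, 6], n_boot=10)


class TestTransitionBiasChisq:
    def test_exact_null_expectation_gives_zero(self):
        res = transition_bias_chisq([(70, 100), (35, 50)], null_p=0.7)
        assert res.chi2 == pytest.approx(0.0)

    def test_single_lineage_hand_value(self):
        res = transition_bias_chisq([(90, 100)], null_p=0.7)
        assert res.chi2 == pytest.approx(400 / 70 + 400 / 30, rel=1e-12)

    def test_p_monotone_in_statistic_at_fixed_df(self):
        weak = transition_bias_chisq([(75, 100), (78, 100)], null_p=0.7)
        strong = transition_bias_chisq([(95, 100), (97, 100)], null_p=0.7)
        assert strong.chi2 > weak.chi2
        assert strong.p_value < weak.p_value
        assert strong.df == weak.df == 1

    def test_empty_lineage_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = transition_bias_chisq([(90, 100), (0, 0)], null_p=0.7)
        assert res.n_lineages == 1

    def test_aggregates_round_counts_per_lineage(self):
        rows = [
            RoundCounts("L1", 1, 40, 50),
            RoundCounts("L1", 2, 50, 50),
            RoundCounts("L2", 1, 60, 100),
        ]
        a = transition_bias_chisq(rows, null_p=0.7)
        b = transition_bias_chisq([(90, 100), (60, 100)], null_p=0.7)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.df == b.df == 1


class TestOlsRatioVsLoad:
    def test_perfect_collinearity(self):
        pts = [(x, 2.0 + 0.5 * x) for x in (1, 2, 3, 4, 5)]
        res = ols_ratio_vs_load(pts)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)

    def test_flat_response(self):
        res = ols_ratio_vs_load([(1, 3.0), (2, 3.0), (5, 3.0)])
        assert res.slope == 0.0 and res.f_stat == 0.0

    def test_matches_normal_equations_oracle(self):
        pts = [(1.0, 2.1), (2.0, 2.9), (3.0, 3.4), (4.0, 5.2), (5.0, 5.4)]
        res = ols_ratio_vs_load(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.df == 3

    def test_constant_load_is_error(self):
        with pytest.raises(FitError):
            ols_ratio_vs_load([(2, 1.0), (2, 2.0), (2, 3.0)])
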