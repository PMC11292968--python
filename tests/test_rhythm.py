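"""Rhythm statistics: ACF, Lomb-Scargle, JTK, integration, multiplicity."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semilunar import (
    EmergenceSeries,
    autocorrelate,
    bh_adjust,
    estimate_period,
    integrate_meta2d,
    jtk_cycle,
    lomb_scargle,
)
from semilunar.exceptions import (
    InsufficientDataError,
    MethodUnavailableError,
    UndefinedStatisticError,
    ValidationError,
)
from semilunar.rhythm import PeriodogramResult, _kendall_s, kendall_s_pvalue


def _series(values, bin_width=24.0):
    return EmergenceSeries(bin_width=bin_width, start_index=0,
                           counts=np.asarray(values, float))


def _brute_force_acf(x, max_lag):
    """Independent oracle: pairwise-complete covariance over observed pairs."""
    obs = ~np.isnan(x)
    m = np.mean(x[obs])
    denom = np.sum((x[obs] - m) ** 2)
    out = []
    for lag in range(max_lag + 1):
        total = 0.0
        for t in range(len(x) - lag):
            if obs[t] and obs[t + lag]:
                total += (x[t] - m) * (x[t + lag] - m)
        out.append(total / denom)
    return np.array(out)


class TestAutocorrelate:
    def test_lag0_is_one(self, cosine_daily):
        acf = autocorrelate(cosine_daily(15), 20)
        assert acf[0] == pytest.approx(1.0)

    def test_cosine_peaks_at_its_period(self, cosine_daily):
        acf = autocorrelate(cosine_daily(15), 40)
        lag = 15
        assert acf[lag] > acf[lag - 2] and acf[lag] > acf[lag + 2]
        assert acf[15] > 0.5

    def test_matches_pairwise_complete_oracle_with_missing(self):
        rng = np.random.default_rng(11)
        x = rng.poisson(6, 82).astype(float)
        x[rng.choice(82, 16, replace=False)] = np.nan  # ~20 % masked
        s = _series(x)
        np.testing.assert_allclose(autocorrelate(s, 30), _brute_force_acf(x, 30),
                                   rtol=1e-12, atol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            autocorrelate(_series([np.nan] * 10), 3)


class TestLombScargle:
    def test_pure_sinusoid_recovered_daily(self, cosine_daily):
        r = lomb_scargle(cosine_daily(15), 3, 35)
        assert abs(r.best_period - 15) <= 15**2 / (4 * 81)  # one period-grid step at 15 d
        assert r.p_value < 1e-6

    def test_pure_sinusoid_recovered_hourly(self):
        t = np.arange(2184)
        y = np.round(10 + 5 * np.cos(2 * np.pi * t / 24))
        r = lomb_scargle(_series(y, bin_width=1.0), 20, 28)
        assert abs(r.best_period - 24) < 0.1
        assert r.p_value < 1e-10

    def test_white_noise_rarely_significant(self):
        hits = 0
        for seed in range(100):
            y = np.random.default_rng(seed).poisson(5, 82).astype(float)
            hits += lomb_scargle(_series(y), 3, 35).p_value <= 0.05
        assert hits <= 10  # p > 0.05 in at least 90 % of null draws

    def test_power_invariant_under_shift_and_scale(self):
        y = np.random.default_rng(3).poisson(8, 82).astype(float)
        base = lomb_scargle(_series(y), 3, 35)
        shifted = lomb_scargle(_series(y + 7), 3, 35)
        scaled = lomb_scargle(_series(3 * y), 3, 35)
        np.testing.assert_allclose(base.statistic, shifted.statistic, rtol=1e-9)
        np.testing.assert_allclose(base.statistic, scaled.statistic, rtol=1e-9)

    def test_too_few_observed_bins_rejected(self):
        vals = np.full(82, np.nan)
        vals[:7] = 1.0
        with pytest.raises(InsufficientDataError):
            lomb_scargle(_series(vals), 3, 35)


class TestJTK:
    def test_cosine_period_recovered(self, cosine_daily):
        r = jtk_cycle(cosine_daily(15), 3, 20)
        assert r.best_period == 15
        assert r.p_value < 1e-4

    def test_exact_null_matches_exhaustive_permutations(self):
        # n = 5 distinct counts vs a tied cosine reference: the exact tail of
        # the Kendall S statistic must equal brute-force enumeration of all
        # 120 orderings
        x = np.array([12.0, 3.0, 7.0, 1.0, 9.0])
        for period, phase in [(4, 0), (5, 1), (3, 2)]:
            ref = np.cos(2 * np.pi * (np.arange(5) - phase) / period)
            _, p = kendall_s_pvalue(x, ref)
            s_obs = abs(_kendall_s(x, ref))
            enum = np.mean([
                abs(_kendall_s(np.array(perm), ref)) >= s_obs
                for perm in permutations(x)
            ])
            assert p == pytest.approx(enum, abs=1e-12)

    def test_long_series_unavailable_falls_back_to_ls(self):
        y = np.round(10 + 5 * np.cos(2 * np.pi * np.arange(2184) / 24))
        s = _series(y, bin_width=1.0)
        with pytest.raises(MethodUnavailableError):
            jtk_cycle(s, 20, 28)
        est = estimate_period(s, layout="hourly")
        assert est.jtk is None
        assert est.tau_integrated == est.ls.best_period

    def test_null_pvalues_super_uniform(self):
        # shuffled counts: empirical false-positive rate below alpha + 2 SE
        alpha, n_shuffles = 0.05, 500
        base = np.random.default_rng(7).poisson(6, 24).astype(float)
        rng = np.random.default_rng(8)
        hits = sum(
            jtk_cycle(_series(rng.permutation(base)), 3, 8).p_value < alpha
            for _ in range(n_shuffles)
        )
        se = np.sqrt(alpha * (1 - alpha) / n_shuffles)
        assert hits / n_shuffles <= alpha + 2 * se

    def test_missing_bins_dropped_pairwise(self, cosine_daily):
        s = cosine_daily(15)
        vals = s.values()
        vals[::7] = np.nan
        r = jtk_cycle(_series(vals), 3, 20)
        assert r.best_period == 15


class TestIntegration:
    def _pg(self, method, period, p):
        return PeriodogramResult(method, np.array([period]), np.array([1.0]), period, p)

    def test_integrated_period_is_arithmetic_mean(self):
        e = integrate_meta2d(self._pg("LS", 14.0, 0.2), self._pg("JTK", 13.0, 0.3))
        assert e.tau_integrated == pytest.approx(13.5)

    def test_identical_method_periods_returned_exactly(self):
        e = integrate_meta2d(self._pg("LS", 15.0, 0.2), self._pg("JTK", 15.0, 0.3))
        assert e.tau_integrated == 15.0

    def test_fisher_combination_values(self):
        # X = -2(ln .01 + ln .04) = 15.648 against chi-square(4)
        e = integrate_meta2d(self._pg("LS", 14.0, 0.01), self._pg("JTK", 13.0, 0.04))
        assert e.p_fisher == pytest.approx(0.00353, abs=2e-4)
        boundary = integrate_meta2d(self._pg("LS", 14.0, 1.0), self._pg("JTK", 13.0, 1.0))
        assert boundary.p_fisher == pytest.approx(1.0)

    def test_single_method_passes_p_through(self):
        e = integrate_meta2d(self._pg("LS", 14.0, 0.07))
        assert e.p_fisher == 0.07 and e.tau_integrated == 14.0


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_input_order_preserved(self):
        q = bh_adjust([0.04, 0.001, 0.5])
        assert q[1] < q[0] < q[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_q_dominates_p_and_stays_in_range(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
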