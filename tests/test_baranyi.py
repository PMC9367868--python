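import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shelfkin as sk
from shelfkin.exceptions import (
    NoGrowthError,
    ParameterError,
    UnreachableThresholdError,
)

from conftest import rk4_baranyi


class TestExplicitSolution:
    def test_initial_value_exact(self, tvc_pad_params):
        assert sk.baranyi_log_count(0.0, tvc_pad_params) == tvc_pad_params.y0

    def test_asymptote(self, tvc_pad_params):
        assert sk.baranyi_log_count(500.0, tvc_pad_params) == \
            pytest.approx(8.09, abs=1e-6)

    def test_monotone_nondecreasing(self, tvc_pad_params):
        t = np.linspace(0, 60, 400)
        y = sk.baranyi_log_count(t, tvc_pad_params)
        assert np.all(np.diff(y) >= -1e-12)

    def test_mid_exponential_matches_ode_oracle(self, tvc_pad_params):
        """y(14) fixed by independent RK4 integration of the differential
        form; the value lies between y0 and ymax."""
        grid = np.linspace(0.0, 14.0, 141)
        oracle = rk4_baranyi(tvc_pad_params, grid)[-1]
        val = sk.baranyi_log_count(14.0, tvc_pad_params)
        assert 5.41 < val < 8.09
        assert val == pytest.approx(oracle, abs=1e-7)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(2, 6), st.floats(0.5, 3.5), st.floats(0.05, 2.0),
           st.floats(0.0, 10.0))
    def test_matches_ode_on_random_draws(self, y0, rise, mu, lag):
        """Explicit solution vs numerical integration across the whole
        growth window, for random valid parameter draws."""
        p = sk.BaranyiParams(y0=y0, ymax=y0 + rise, mu=mu, lag=lag)
        horizon = 3.0 * (lag + rise / mu)
        grid = np.linspace(0.0, horizon, 100)
        assert np.max(np.abs(sk.baranyi_log_count(grid, p)
                             - rk4_baranyi(p, grid))) < 1e-6

    @given(st.floats(2, 8), st.floats(0.1, 4), st.floats(0.01, 9),
           st.floats(0, 20))
    @settings(derandomize=True)
    def test_y0_exact_property(self, y0, rise, mu, lag):
        p = sk.BaranyiParams(y0=y0, ymax=y0 + rise, mu=mu, lag=lag)
        assert sk.baranyi_log_count(0.0, p) == y0

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            sk.BaranyiParams(y0=8.0, ymax=7.0, mu=0.5)
        with pytest.raises(ParameterError):
            sk.BaranyiParams(y0=5.0, ymax=8.0, mu=-0.1)
        with pytest.raises(ParameterError):
            sk.BaranyiParams(y0=5.0, ymax=8.0, mu=0.5, lag=-1.0)


class TestTimeToThreshold:
    def test_linear_phase_no_lag(self):
        p = sk.BaranyiParams(y0=5.0, ymax=1e6, mu=0.5, lag=0.0)
        assert sk.time_to_threshold(p, 7.0) == pytest.approx(4.0, abs=1e-9)

    def test_lag_shifts_crossing(self):
        # the adjustment function approaches t - lag asymptotically, so the
        # crossing sits just under y0 rise + lag
        p = sk.BaranyiParams(y0=5.0, ymax=1e6, mu=0.5, lag=2.0)
        assert sk.time_to_threshold(p, 7.0) == pytest.approx(6.0, abs=0.01)

    def test_braking_near_capacity_slows_crossing(self):
        """Bisection oracle: with ymax = 7.5 the approach to 7 is slowed
        by the braking term, so the crossing is strictly after 4 d."""
        p = sk.BaranyiParams(y0=5.0, ymax=7.5, mu=0.5, lag=0.0)
        t = sk.time_to_threshold(p, 7.0)
        assert t > 4.0
        # bisection on the explicit curve as an independent check
        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if sk.baranyi_log_count(mid, p) < 7.0:
                lo = mid
            else:
                hi = mid
        assert t == pytest.approx((lo + hi) / 2, abs=1e-9)

    def test_threshold_below_y0_warns_and_returns_zero(self, tvc_pad_params):
        with pytest.warns(UserWarning):
            assert sk.time_to_threshold(tvc_pad_params, 5.0) == 0.0

    def test_threshold_above_ymax_unreachable(self, tvc_pad_params):
        with pytest.raises(UnreachableThresholdError):
            sk.time_to_threshold(tvc_pad_params, 9.0)

    def test_threshold_at_ymax_infinite(self, tvc_pad_params):
        assert sk.time_to_threshold(tvc_pad_params, 8.09) == np.inf

    @given(st.floats(0.5, 5.0), st.floats(0.1, 2.0))
    @settings(derandomize=True, max_examples=25)
    def test_monotone_in_lag_and_mu(self, lag, mu):
        base = sk.BaranyiParams(y0=5.0, ymax=9.0, mu=mu, lag=lag)
        longer_lag = sk.BaranyiParams(y0=5.0, ymax=9.0, mu=mu, lag=lag + 1.0)
        faster = sk.BaranyiParams(y0=5.0, ymax=9.0, mu=mu * 1.5, lag=lag)
        t0 = sk.time_to_threshold(base, 7.0)
        assert sk.time_to_threshold(longer_lag, 7.0) > t0
        assert sk.time_to_threshold(faster, 7.0) < t0


class TestFitting:
    def test_noiseless_self_inversion(self):
        truth = sk.BaranyiParams(y0=4.54, ymax=8.48, mu=0.294, lag=2.88)
        t = np.linspace(0.0, 35.0, 15)
        curve = sk.gen_growth_curve(truth, t, 0.0, 0)
        res = sk.fit_baranyi(curve, with_lag=True)
        for got, want in zip(res.params.as_array(), truth.as_array()):
            assert got == pytest.approx(want, rel=1e-6)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_fit_within_three_se(self):
        truth = sk.BaranyiParams(y0=4.54, ymax=8.48, mu=0.294, lag=2.88)
        t = np.linspace(0.0, 30.0, 12)
        curve = sk.gen_growth_curve(truth, t, 0.15, 7)
        res = sk.fit_baranyi(curve, with_lag=True)
        est = res.params.as_array()[:len(res.param_names)]
        tru = truth.as_array()[:len(res.param_names)]
        assert np.all(np.abs(est - tru) <= 3.0 * res.bse + 1e-12)

    def test_decreasing_series_is_no_growth(self):
        curve = sk.GrowthCurve(np.arange(5.0), np.array([7, 6.5, 6, 5.5, 5.0]))
        with pytest.raises(NoGrowthError):
            sk.fit_baranyi(curve)

    def test_auto_drops_insignificant_lag(self):
        truth = sk.BaranyiParams(y0=4.5, ymax=8.5, mu=0.4, lag=None)
        t = np.linspace(0.0, 25.0, 14)
        curve = sk.gen_growth_curve(truth, t, 0.05, 3)
        res = sk.fit_baranyi(curve, with_lag="auto")
        assert res.params.lag is None

    def test_too_few_observations(self):
        curve = sk.GrowthCurve([0.0, 1.0, 2.0], [5.0, 6.0, 7.0])
        with pytest.raises(ParameterError):
            sk.BaranyiModel.from_curve(curve).fit(with_lag=True)

    def test_from_dataframe_averages_replicates(self):
        import pandas as pd
        truth = sk.BaranyiParams(y0=5.0, ymax=8.0, mu=0.5, lag=1.0)
        t = np.linspace(0, 15, 10)
        y = sk.baranyi_log_count(t, truth)
        df = pd.DataFrame({
            "time_d": np.tile(t, 2),
            "log10_count": np.concatenate([y + 0.1, y - 0.1]),
            "organism": "TVC", "packaging": "MAP", "temperature_C": 5.0,
            "replicate": [1] * 10 + [2] * 10})
        res = sk.BaranyiModel.from_dataframe(df).fit(with_lag=True)
        assert res.params.mu == pytest.approx(0.5, rel=1e-5)
        assert res.model.curve.organism == "TVC"

    def test_summary_mentions_r_squared(self, tvc_pad_params):
        t = np.linspace(0, 40, 12)
        curve = sk.gen_growth_curve(tvc_pad_params, t, 0.0, 0)
        res = sk.fit_baranyi(curve, with_lag=True)
        assert "R^2" in res.summary()
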