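import numpy as np
import pytest

import shelfkin as sk
from shelfkin.exceptions import NoGrowthError, ParameterError, ProfileError

from conftest import rk4_baranyi

TREF = sk.TREF_DEFAULT_K
R = sk.R_GAS


def square_wave(low_c=2.0, high_c=8.0, cycle_d=2.0, duration_d=12.0):
    segs, t = [], 0.0
    while t < duration_d - 1e-9:
        segs.append((t, t + cycle_d / 2, low_c))
        segs.append((t + cycle_d / 2, t + cycle_d, high_c))
        t += cycle_d
    return sk.TemperatureProfile.from_celsius_segments(segs)


class TestProfile:
    def test_contiguity_enforced(self):
        with pytest.raises(ProfileError):
            sk.TemperatureProfile.from_celsius_segments(
                [(0.0, 2.0, 4.0), (3.0, 5.0, 6.0)])

    def test_must_start_at_zero(self):
        with pytest.raises(ProfileError):
            sk.TemperatureProfile.from_celsius_segments([(1.0, 2.0, 4.0)])

    def test_temperature_range_enforced(self):
        with pytest.raises(ProfileError):
            sk.TemperatureProfile.from_celsius_segments([(0.0, 2.0, 30.0)])

    def test_lookup(self):
        prof = square_wave()
        assert prof.temperature_at(0.1) == pytest.approx(275.15)
        assert prof.temperature_at(1.5) == pytest.approx(281.15)


class TestEffectiveTemperature:
    def test_constant_profile_identity(self):
        prof = sk.TemperatureProfile.constant(10.0, 4.8)
        for ea in (50_000.0, 113_100.0):
            teff = sk.effective_temperature(prof, ea, TREF)
            assert teff - 273.15 == pytest.approx(4.8, abs=1e-12)

    def test_square_wave_exceeds_arithmetic_mean(self):
        """Direct oracle: average the Arrhenius factor over the two
        levels and invert; Jensen's inequality puts Teff above 5 degC."""
        prof = square_wave(low_c=2.0, high_c=8.0)
        ea = 113_100.0
        teff = sk.effective_temperature(prof, ea, TREF)
        f = 0.5 * (np.exp(-ea / R * (1 / 275.15 - 1 / TREF))
                   + np.exp(-ea / R * (1 / 281.15 - 1 / TREF)))
        oracle = 1.0 / (1.0 / TREF - R / ea * np.log(f))
        assert teff == pytest.approx(oracle, abs=1e-9)
        assert teff - 273.15 > 5.0

    def test_zero_ea_limit_is_weighted_mean(self):
        prof = sk.TemperatureProfile.from_celsius_segments(
            [(0.0, 3.0, 2.0), (3.0, 4.0, 10.0)])
        teff = sk.effective_temperature(prof, 0.0, TREF)
        assert teff - 273.15 == pytest.approx(4.0)

    def test_bounds_and_mean_inequality(self):
        prof = square_wave(low_c=1.0, high_c=9.0, cycle_d=3.0)
        for ea in (20_000.0, 80_000.0, 150_000.0):
            teff = sk.effective_temperature(prof, ea, TREF)
            assert 274.15 <= teff <= 282.15
            assert teff >= np.average(prof.temperatures_k,
                                      weights=prof.durations)

    def test_segment_permutation_invariance(self):
        a = sk.TemperatureProfile.from_celsius_segments(
            [(0.0, 2.0, 2.0), (2.0, 4.0, 9.0), (4.0, 6.0, 5.0)])
        b = sk.TemperatureProfile.from_celsius_segments(
            [(0.0, 2.0, 9.0), (2.0, 4.0, 5.0), (4.0, 6.0, 2.0)])
        assert sk.effective_temperature(a, 100_000.0, TREF) == \
            pytest.approx(sk.effective_temperature(b, 100_000.0, TREF),
                          abs=1e-12)


class TestDynamicGrowth:
    def rate_model(self, kref=0.4, ea_kj=113.1):
        return sk.ArrheniusResults.from_constants(kref=kref, ea_kj=ea_kj)

    def test_constant_profile_reduces_to_explicit_solution(self):
        rm = self.rate_model()
        params = sk.BaranyiParams(y0=5.0, ymax=8.5, mu=rm.kref, lag=3.0)
        prof = sk.TemperatureProfile.constant(20.0, 4.0)
        t, y = sk.predict_growth_dynamic(params, rm, prof)
        assert np.max(np.abs(y - sk.baranyi_log_count(t, params))) < 1e-6

    def test_two_segment_profile_matches_rk4_oracle(self):
        rm = self.rate_model()
        params = sk.BaranyiParams(y0=5.0, ymax=8.5, mu=rm.kref, lag=2.0)
        prof = sk.TemperatureProfile.from_celsius_segments(
            [(0.0, 6.0, 2.0), (6.0, 14.0, 9.0)])
        t, y = sk.predict_growth_dynamic(params, rm, prof, n_points=141)

        def mu_of_t(tt):
            return rm.predict(prof.temperature_at(min(tt, 14.0 - 1e-12)))

        oracle = rk4_baranyi(params, t, mu_of_t=mu_of_t)
        assert np.max(np.abs(y - oracle)) < 1e-6

    def test_zero_lag_starts_growth_immediately(self):
        rm = self.rate_model()
        params = sk.BaranyiParams(y0=5.0, ymax=8.5, mu=rm.kref, lag=None)
        prof = sk.TemperatureProfile.constant(10.0, 4.0)
        t, y = sk.predict_growth_dynamic(params, rm, prof)
        assert np.max(np.abs(y - sk.baranyi_log_count(t, params))) < 1e-6
        # growth visible from the first step
        assert y[1] > y[0]

    def test_trajectory_monotone_and_bounded(self):
        rm = self.rate_model()
        params = sk.BaranyiParams(y0=5.0, ymax=8.0, mu=rm.kref, lag=1.0)
        t, y = sk.predict_growth_dynamic(params, rm, square_wave())
        assert np.all(np.diff(y) >= -1e-10)
        assert np.all(y <= 8.0 + 1e-9)


class TestApparentRate:
    def test_recovers_rate_at_reference_temperature(self):
        rm = sk.ArrheniusResults.from_constants(kref=0.5, ea_kj=113.1)
        params = sk.BaranyiParams(y0=5.0, ymax=8.5, mu=0.5, lag=2.0)
        prof = sk.TemperatureProfile.constant(16.0, 4.0)
        t, y = sk.predict_growth_dynamic(params, rm, prof, n_points=25)
        res = sk.apparent_growth_rate(t, y, with_lag=True)
        assert res.mu == pytest.approx(0.5, abs=1e-4)

    def test_nonisothermal_rate_matches_fit_to_oracle(self):
        rm = sk.ArrheniusResults.from_constants(kref=0.4, ea_kj=113.1)
        params = sk.BaranyiParams(y0=5.0, ymax=8.5, mu=0.4, lag=2.0)
        prof = sk.TemperatureProfile.from_celsius_segments(
            [(0.0, 5.0, 2.0), (5.0, 12.0, 8.0)])
        t, y = sk.predict_growth_dynamic(params, rm, prof, n_points=25)

        def mu_of_t(tt):
            return rm.predict(prof.temperature_at(min(tt, 12.0 - 1e-12)))

        oracle = rk4_baranyi(params, t, mu_of_t=mu_of_t)
        k_impl = sk.apparent_growth_rate(t, y, with_lag=True).mu
        k_oracle = sk.apparent_growth_rate(t, oracle, with_lag=True).mu
        assert k_impl == pytest.approx(k_oracle, abs=1e-3)

    def test_flat_trajectory_is_no_growth(self):
        with pytest.raises(NoGrowthError):
            sk.apparent_growth_rate(np.arange(8.0), np.full(8, 5.0))


class TestRelativeError:
    @pytest.mark.parametrize("k_exp, k_pred, re_int", [
        (0.348, 0.398, 14),   # pad-augmented MAP, total viable count
        (0.551, 0.524, 5),    # plain MAP, total viable count
    ])
    def test_published_rate_pairs(self, k_exp, k_pred, re_int):
        res = sk.relative_error(k_exp, k_pred)
        assert res.re_percent_rounded == re_int

    def test_equal_inputs_zero(self):
        res = sk.relative_error(0.4, 0.4)
        assert res.re_percent == 0.0
        assert res.pass_20pct

    def test_magnitude_and_pass_flag(self):
        res = sk.relative_error(0.4, 0.5)
        assert res.re_percent == pytest.approx(25.0)
        assert not res.pass_20pct

    def test_nonpositive_experimental_rejected(self):
        with pytest.raises(ParameterError):
            sk.relative_error(0.0, 0.4)
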