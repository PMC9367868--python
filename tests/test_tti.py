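import math

import numpy as np
import pytest
from scipy import optimize

import shelfkin as sk
from shelfkin.exceptions import (
    CalibrationError,
    DegenerateSeriesError,
    DesignError,
    ParameterError,
)
from shelfkin.tti import TTIGlobalModel, TTILogisticModel

TREF = sk.TREF_DEFAULT_K


def make_series(sums, times=None, ab_min=None, ab_max=None):
    times = range(len(sums)) if times is None else times
    readings = [sk.ColorReading(time_d=float(t), a=s / 2, b=s / 2)
                for t, s in zip(times, sums)]
    return sk.TTISeries(readings=readings, ab_min=ab_min, ab_max=ab_max)


class TestNormalization:
    def test_extremes_map_to_unit_interval(self):
        series = make_series([-20.0, 10.0, 60.0])
        norm = sk.normalize_response(series)
        assert norm[0, 1] == 0.0
        assert norm[-1, 1] == 1.0

    def test_midpoint(self):
        series = make_series([20.0], ab_min=-20.0, ab_max=60.0)
        assert sk.normalize_response(series)[0, 1] == pytest.approx(0.5)

    def test_external_calibration_clips(self):
        series = make_series([-30.0, 70.0], ab_min=-20.0, ab_max=60.0)
        norm = sk.normalize_response(series)
        assert norm[0, 1] == 0.0 and norm[1, 1] == 1.0

    def test_bad_calibration(self):
        with pytest.raises(CalibrationError):
            make_series([0.0, 10.0], ab_min=5.0, ab_max=5.0)


class TestLogistic:
    def test_half_response_at_k1(self):
        assert sk.logistic_response(8.03, 8.03, 1.49) == pytest.approx(0.5)

    def test_endpoint_closed_form(self):
        k1, k2 = 8.03, 1.49
        assert sk.logistic_response(k1 + k2 * math.log(4), k1, k2) == \
            pytest.approx(0.8, rel=1e-12)

    def test_endpoint_crossing_by_root_finding(self):
        """The 0.8 end point of the M-25U label at 5 degC, found
        numerically on the logistic with its measured constants."""
        k1, k2 = 8.03, 1.49
        t80 = optimize.brentq(
            lambda t: sk.logistic_response(t, k1, k2) - 0.8, 0.0, 50.0)
        assert t80 == pytest.approx(10.1, abs=0.05)

    def test_strictly_increasing(self):
        t = np.linspace(0, 30, 100)
        y = sk.logistic_response(t, 10.0, 2.0)
        assert np.all(np.diff(y) > 0) and np.all((y > 0) & (y < 1))

    def test_invalid_constants(self):
        with pytest.raises(ParameterError):
            sk.logistic_response(1.0, -1.0, 2.0)


class TestLogisticFit:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 25, 20)
        y = sk.logistic_response(t, 10.0, 2.0)
        p = sk.fit_logistic(np.column_stack([t, y]))
        assert p.k1 == pytest.approx(10.0, rel=1e-6)
        assert p.k2 == pytest.approx(2.0, rel=1e-6)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 25, 20)
        y = np.clip(sk.logistic_response(t, 10.0, 2.0)
                    + rng.normal(0, 0.03, t.size), 0, 1)
        res = TTILogisticModel(t, y).fit()
        assert abs(res.k1 - 10.0) <= 3 * res.bse[0]
        assert abs(res.k2 - 2.0) <= 3 * res.bse[1]

    def test_flat_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            TTILogisticModel(np.arange(6.0), np.full(6, 0.5))

    def test_too_few_points(self):
        with pytest.raises(DesignError):
            TTILogisticModel([0, 1, 2, 3], [0, 0.3, 0.7, 1.0])


class TestGlobalModel:
    def test_reference_constants_at_unit_concentration(self, m_type_global):
        k1, k2 = m_type_global.predict_k1k2(1.0, TREF)
        assert (k1, k2) == (128.6, 25.7)

    def test_m25_cold_prediction_direct_evaluation(self, m_type_global):
        expected_k1 = (128.6 * 25 ** -0.861
                       * math.exp(97100.0 / sk.R_GAS
                                  * (1 / 278.15 - 1 / TREF)))
        k1, _ = m_type_global.predict_k1k2(25.0, 278.15)
        assert k1 == pytest.approx(expected_k1, rel=1e-12)
        assert k1 == pytest.approx(8.03, rel=0.2)  # vs the measured value

    def test_lp150_warm_prediction_close_to_measurement(self, lp_type_global):
        k1, _ = lp_type_global.predict_k1k2(150.0, 283.15)
        assert k1 == pytest.approx(1.81, rel=0.10)

    def test_forward_predictions_cover_measured_tables(self):
        """Global-model forward predictions reproduce >= 80% of the
        measured k1/k2 constants across both chemistries within the
        global-fit residual scale of 35%."""
        tab = sk.datasets.tti_rate_constants()
        models = sk.datasets.tti_global_models()
        n_ok = 0
        for _, row in tab.iterrows():
            k1p, k2p = models[row.tti_type].predict_k1k2(
                row.enzyme_units, row.temperature_C + 273.15)
            n_ok += abs(k1p - row.k1) / row.k1 <= 0.35
            n_ok += abs(k2p - row.k2) / row.k2 <= 0.35
        assert n_ok / (2 * len(tab)) >= 0.80

    def test_exact_recovery_from_synthetic_grid(self):
        truth = sk.TTIGlobalResults(ea=100_000.0, k1ref_c1=100.0,
                                    k2ref_c1=20.0, alpha=0.9, beta=1.05)
        recs = [(c, t_c, *truth.predict_k1k2(c, t_c + 273.15))
                for c in (5, 25, 100) for t_c in (0.0, 5.0, 10.0)]
        fit = TTIGlobalModel(recs).fit()
        assert fit.ea == pytest.approx(100_000.0, rel=1e-6)
        assert fit.k1ref_c1 == pytest.approx(100.0, rel=1e-6)
        assert fit.k2ref_c1 == pytest.approx(20.0, rel=1e-6)
        assert fit.alpha == pytest.approx(0.9, rel=1e-6)
        assert fit.beta == pytest.approx(1.05, rel=1e-6)

    def test_m_type_table_fit_matches_published_ea(self):
        tab = sk.datasets.tti_rate_constants()
        m = tab[tab.tti_type == "M"]
        fit = TTIGlobalModel(
            list(zip(m.enzyme_units, m.temperature_C, m.k1, m.k2)),
            tti_type="M").fit()
        assert fit.ea_kj == pytest.approx(97.1, rel=0.20)

    def test_single_concentration_rejected(self):
        recs = [(25.0, t, 10.0 / (t + 1), 2.0 / (t + 1))
                for t in (0.0, 5.0, 10.0)]
        with pytest.raises(DesignError):
            TTIGlobalModel(recs)

    def test_nls_refinement_close_to_loglinear(self):
        truth = sk.TTIGlobalResults(ea=100_000.0, k1ref_c1=100.0,
                                    k2ref_c1=20.0, alpha=0.9, beta=1.0)
        recs, resp = [], []
        times = np.linspace(0, 40, 15)
        for c in (5, 25, 100):
            for t_c in (0.0, 5.0, 10.0):
                k1, k2 = truth.predict_k1k2(c, t_c + 273.15)
                recs.append((c, t_c, k1, k2))
                resp += [(c, t_c, t, sk.logistic_response(t, k1, k2))
                         for t in times]
        model = TTIGlobalModel(recs)
        refined = model.fit_to_responses(resp)
        assert refined.ea == pytest.approx(100_000.0, rel=1e-3)
        assert refined.alpha == pytest.approx(0.9, rel=1e-3)


class TestResponseTime:
    def test_half_endpoint_is_k1(self, m_type_global):
        k1, _ = m_type_global.predict_k1k2(25.0, TREF)
        assert m_type_global.response_time(25.0, TREF, endpoint=0.5) == \
            pytest.approx(k1, rel=1e-12)

    def test_visual_endpoint_closed_form(self, m_type_global):
        k1, k2 = m_type_global.predict_k1k2(25.0, TREF)
        assert m_type_global.response_time(25.0, TREF) == \
            pytest.approx(k1 + k2 * math.log(4), rel=1e-12)

    def test_monotone_decreasing_in_temperature(self, m_type_global):
        grid = 273.15 + np.linspace(0, 10, 21)
        times = m_type_global.response_time(25.0, grid)
        assert np.all(np.diff(times) < 0)

    def test_roundtrip_inversion(self, m_type_global):
        """response_time then logistic_response returns the end point."""
        for endpoint in (0.2, 0.5, 0.8, 0.95):
            t = m_type_global.response_time(25.0, 276.15, endpoint=endpoint)
            k1, k2 = m_type_global.predict_k1k2(25.0, 276.15)
            assert sk.logistic_response(t, k1, k2) == \
                pytest.approx(endpoint, abs=1e-9)

    def test_decreasing_in_concentration_and_temperature(self, m_type_global):
        k1_a, k2_a = m_type_global.predict_k1k2(10.0, 275.15)
        k1_b, k2_b = m_type_global.predict_k1k2(50.0, 275.15)
        k1_c, k2_c = m_type_global.predict_k1k2(10.0, 281.15)
        assert k1_b < k1_a and k2_b < k2_a
        assert k1_c < k1_a and k2_c < k2_a

    def test_nonpositive_concentration(self, m_type_global):
        with pytest.raises(ParameterError):
            m_type_global.predict_k1k2(0.0, TREF)
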