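"""Enzymatic time-temperature-integrator (TTI) response kinetics.

An enzymatic TTI label changes color irreversibly as a lipase hydrolyses
its substrate; the color state is summarized by the CIELab sum (a + b),
min-max normalized to a response in [0, 1].  Against storage time the
response is logistic,

    norm(a+b)(t) = 1 / (1 + exp((k1 - t) / k2)),

so k1 (days) is the inflection time and k2 (days) the spread; the visual
end point of the label corresponds to a response of 0.8.

Across enzyme concentration C and temperature T the two constants follow a
global power-law/Arrhenius model,

    k_i(C, T) = k_iref(C=1U) * C^(-alpha_i) * exp(+(Ea/R)(1/T - 1/Tref)),

with a single activation energy per TTI chemistry.  k1 and k2 are
time-like: they shrink as temperature (or enzyme load) rises, hence the
positive sign on the reciprocal-temperature term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .arrhenius import R_GAS, TREF_DEFAULT_K
from .exceptions import (
    CalibrationError,
    DegenerateSeriesError,
    DesignError,
    FittingError,
    ParameterError,
)

TTI_TYPES = ("M", "LP")
ENDPOINT_DEFAULT = 0.8

__all__ = [
    "ColorReading",
    "TTISeries",
    "LogisticParams",
    "TTILogisticModel",
    "TTILogisticResults",
    "TTIGlobalModel",
    "TTIGlobalResults",
    "normalize_response",
    "logistic_response",
    "fit_logistic",
    "fit_global_model",
    "predict_k1k2",
    "response_time",
]


@dataclass(frozen=True)
class ColorReading:
    """One CIELab color measurement of a TTI label."""

    time_d: float
    a: float
    b: float

    def __post_init__(self):
        if not (-60.0 <= self.a <= 60.0 and -60.0 <= self.b <= 60.0):
            raise ParameterError("CIELab a and b must lie within [-60, 60]")
        if not np.isfinite(self.time_d):
            raise ParameterError("time must be finite")

    @property
    def ab(self) -> float:
        return self.a + self.b


@dataclass
class TTISeries:
    """Color readings of one TTI label at one enzyme load and temperature.

    ``ab_min``/``ab_max`` are the calibration bounds for normalization.
    When not given they default to the series' own extremes (a per-batch
    self-calibration); a calibration file can override them.
    """

    readings: list[ColorReading]
    tti_type: str | None = None
    enzyme_units: float | None = None
    temperature_c: float | None = None
    ab_min: float | None = None
    ab_max: float | None = None

    def __post_init__(self):
        if self.tti_type is not None and self.tti_type not in TTI_TYPES:
            raise ParameterError(f"unknown TTI type {self.tti_type!r}")
        times = [r.time_d for r in self.readings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("readings must be strictly time-sorted")
        sums = [r.ab for r in self.readings]
        if self.ab_min is None:
            self.ab_min = min(sums)
        if self.ab_max is None:
            self.ab_max = max(sums)
        if not self.ab_max > self.ab_min:
            raise CalibrationError(
                f"ab_max ({self.ab_max}) must exceed ab_min ({self.ab_min})")

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_d for r in self.readings])


def normalize_response(series: TTISeries) -> np.ndarray:
    """Min-max normalized response, one (time, norm) row per reading.

    norm = ((a+b) - ab_min) / (ab_max - ab_min), clipped to [0, 1].
    """
    span = series.ab_max - series.ab_min
    rows = [(r.time_d, min(1.0, max(0.0, (r.ab - series.ab_min) / span)))
            for r in series.readings]
    return np.array(rows)


@dataclass(frozen=True)
class LogisticParams:
    """Per-label logistic constants: k1 = inflection time, k2 = spread."""

    k1: float
    k2: float
    rsquared: float | None = None

    def __post_init__(self):
        if not (self.k1 > 0 and self.k2 > 0):
            raise ParameterError("k1 and k2 must be positive")


def logistic_response(t, k1: float, k2: float):
    """Rising logistic response 1/(1 + exp((k1 - t)/k2)); 0.5 at t = k1."""
    if not (k1 > 0 and k2 > 0):
        raise ParameterError("k1 and k2 must be positive")
    t_arr = np.asarray(t, dtype=float)
    from scipy.special import expit
    out = expit((t_arr - k1) / k2)
    return out if out.shape else float(out)


class TTILogisticModel:
    """Logistic response model for one normalized TTI series.

    Accepts either a (time, norm) array (e.g. from
    :func:`normalize_response`) or a :class:`TTISeries` via
    :meth:`from_series`.  Requires >= 5 points spanning both tails of the
    sigmoid.
    """

    def __init__(self, times, responses):
        t = np.asarray(times, dtype=float)
        y = np.asarray(responses, dtype=float)
        if t.size < 5:
            raise DesignError(f"need >= 5 points, got {t.size}")
        if np.ptp(y) < 0.5:
            raise DegenerateSeriesError(
                "response series does not span the sigmoid (range < 0.5)")
        self.times, self.responses = t, y

    @classmethod
    def from_series(cls, series: TTISeries) -> "TTILogisticModel":
        norm = normalize_response(series)
        return cls(norm[:, 0], norm[:, 1])

    def fit(self) -> "TTILogisticResults":
        t, y = self.times, self.responses
        # start: k1 at the 0.5 crossing, k2 from the central slope
        k1_0 = float(np.interp(0.5, y, t)) if np.all(np.diff(y) >= 0) else \
            float(t[np.argmin(np.abs(y - 0.5))])
        k1_0 = min(max(k1_0, 1e-3), t[-1] * 2)
        k2_0 = max((t[-1] - t[0]) / 10.0, 1e-3)

        def resid(theta):
            lk1, lk2 = theta
            return logistic_response(t, math.exp(lk1), math.exp(lk2)) - y

        sol = optimize.least_squares(resid, [math.log(k1_0), math.log(k2_0)],
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise FittingError("logistic fit did not converge", incumbent=sol.x)
        k1, k2 = np.exp(sol.x)
        res = -sol.fun
        ss_res = float(sol.fun @ sol.fun)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        # delta method: se(k) = k * se(ln k)
        dof = max(t.size - 2, 1)
        s2 = ss_res / dof
        try:
            cov_log = np.linalg.inv(sol.jac.T @ sol.jac) * s2
            bse = np.array([k1, k2]) * np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(2, np.nan)
        return TTILogisticResults(
            params=LogisticParams(k1=float(k1), k2=float(k2), rsquared=r2),
            bse=bse, resid=res, nobs=t.size)


@dataclass
class TTILogisticResults:
    params: LogisticParams
    bse: np.ndarray
    resid: np.ndarray
    nobs: int

    @property
    def k1(self) -> float:
        return self.params.k1

    @property
    def k2(self) -> float:
        return self.params.k2

    @property
    def rsquared(self) -> float:
        return self.params.rsquared

    def predict(self, t):
        return logistic_response(t, self.k1, self.k2)

    def response_time(self, endpoint: float = ENDPOINT_DEFAULT) -> float:
        """Time to the given response level: t = k1 + k2 ln(e/(1-e))."""
        if not 0.0 < endpoint < 1.0:
            raise ParameterError("endpoint must lie in (0, 1)")
        return self.k1 + self.k2 * math.log(endpoint / (1.0 - endpoint))

    def summary(self) -> str:
        return (f"TTI logistic response fit:  k1 = {self.k1:.3f} d "
                f"(se {self.bse[0]:.3f}),  k2 = {self.k2:.3f} d "
                f"(se {self.bse[1]:.3f}),  R^2 = {self.rsquared:.4f}")


def fit_logistic(norm_series) -> LogisticParams:
    """Fit the logistic response to an (n, 2) array of (days, norm)."""
    arr = np.asarray(norm_series, dtype=float)
    return TTILogisticModel(arr[:, 0], arr[:, 1]).fit().params


# --------------------------------------------------------------------------
# Global concentration-temperature model
# --------------------------------------------------------------------------

class TTIGlobalModel:
    """Global model of k1, k2 across enzyme concentration and temperature.

    Built from per-label logistic fits as (C, T_celsius, LogisticParams)
    records (or (C, T, k1, k2) tuples).  The default estimator is a joint
    log-linear least squares of ln k1 and ln k2 on ln C and the reciprocal
    temperature deviation, with a shared Ea slope and separate intercepts
    and concentration exponents for k1 and k2.  A direct nonlinear fit to
    normalized responses is available through
    :meth:`fit_to_responses`.
    """

    def __init__(self, records, tti_type=None, tref_k=TREF_DEFAULT_K):
        rows = []
        for rec in records:
            if len(rec) == 3 and isinstance(rec[2], LogisticParams):
                c, t_c, p = rec
                rows.append((float(c), float(t_c), p.k1, p.k2))
            else:
                c, t_c, k1, k2 = rec
                rows.append((float(c), float(t_c), float(k1), float(k2)))
        arr = np.array(rows)
        if arr.size == 0:
            raise DesignError("no records")
        if np.any(arr[:, 0] <= 0) or np.any(arr[:, 2:] <= 0):
            raise ParameterError("concentrations and constants must be positive")
        if len(np.unique(arr[:, 0])) < 3 or len(np.unique(arr[:, 1])) < 3:
            raise DesignError(
                "need >= 3 distinct concentrations and >= 3 distinct temperatures")
        self.records = arr
        self.tti_type = tti_type
        self.tref_k = float(tref_k)

    def fit(self, shared_ea=True) -> "TTIGlobalResults":
        c, t_c, k1, k2 = self.records.T
        x = 1.0 / (t_c + 273.15) - 1.0 / self.tref_k
        lnc = np.log(c)
        n = c.size
        y = np.concatenate([np.log(k1), np.log(k2)])
        zeros = np.zeros(n)
        ones = np.ones(n)
        if shared_ea:
            # columns: [i1, i2, lnC(k1), lnC(k2), x(shared)]
            X = np.block([
                [ones[:, None], zeros[:, None], lnc[:, None], zeros[:, None], x[:, None]],
                [zeros[:, None], ones[:, None], zeros[:, None], lnc[:, None], x[:, None]],
            ])
        else:
            X = np.block([
                [ones[:, None], zeros[:, None], lnc[:, None], zeros[:, None],
                 x[:, None], zeros[:, None]],
                [zeros[:, None], ones[:, None], zeros[:, None], lnc[:, None],
                 zeros[:, None], x[:, None]],
            ])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("rank-deficient design for the global model")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fittedvalues = X @ beta
        ss_res = float(((y - fittedvalues) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if shared_ea:
            i1, i2, a1, a2, slope = beta
            ea1 = ea2 = R_GAS * slope
        else:
            i1, i2, a1, a2, s1, s2 = beta
            ea1, ea2 = R_GAS * s1, R_GAS * s2
        return TTIGlobalResults(
            tti_type=self.tti_type, tref_k=self.tref_k,
            ea=float(ea1), ea_k2=float(ea2),
            k1ref_c1=float(math.exp(i1)), k2ref_c1=float(math.exp(i2)),
            alpha=float(-a1), beta=float(-a2), rsquared=float(r2),
            nobs=2 * n)

    def fit_to_responses(self, response_records) -> "TTIGlobalResults":
        """Direct nonlinear fit of the global model to normalized responses.

        ``response_records`` is an iterable of (C, T_celsius, time_d, norm)
        rows.  Starts from the log-linear solution and refines all five
        parameters (shared Ea) by least squares on the responses.
        """
        arr = np.asarray(list(response_records), dtype=float)
        c, t_c, t, y = arr.T
        x = 1.0 / (t_c + 273.15) - 1.0 / self.tref_k
        start = self.fit(shared_ea=True)
        theta0 = np.array([
            math.log(start.k1ref_c1), math.log(start.k2ref_c1),
            start.alpha, start.beta, start.ea])

        def resid(theta):
            lk1, lk2, al, be, ea = theta
            k1 = np.exp(lk1 - al * np.log(c) + (ea / R_GAS) * x)
            k2 = np.exp(lk2 - be * np.log(c) + (ea / R_GAS) * x)
            from scipy.special import expit
            return expit((t - k1) / k2) - y

        sol = optimize.least_squares(resid, theta0, xtol=1e-12, ftol=1e-12)
        if not np.all(np.isfinite(sol.x)):
            raise FittingError("global response fit did not converge",
                               incumbent=sol.x)
        lk1, lk2, al, be, ea = sol.x
        ss_res = float(sol.fun @ sol.fun)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return TTIGlobalResults(
            tti_type=self.tti_type, tref_k=self.tref_k, ea=float(ea),
            ea_k2=float(ea), k1ref_c1=float(math.exp(lk1)),
            k2ref_c1=float(math.exp(lk2)), alpha=float(al), beta=float(be),
            rsquared=1.0 - ss_res / ss_tot, nobs=y.size)


@dataclass
class TTIGlobalResults:
    """Fitted (or published) global TTI model parameters.

    ``k1ref_c1``/``k2ref_c1`` are the constants (days) at 1 enzyme unit and
    Tref; ``alpha``/``beta`` the concentration exponents; ``ea`` the
    activation energy (J/mol).  ``ea_k2`` differs from ``ea`` only when the
    model was fitted without a shared Ea.
    """

    ea: float
    k1ref_c1: float
    k2ref_c1: float
    alpha: float
    beta: float
    tref_k: float = TREF_DEFAULT_K
    tti_type: str | None = None
    ea_k2: float | None = None
    rsquared: float | None = None
    nobs: int | None = None

    def __post_init__(self):
        if min(self.ea, self.k1ref_c1, self.k2ref_c1) <= 0:
            raise ParameterError("Ea and reference constants must be positive")
        if self.ea_k2 is None:
            self.ea_k2 = self.ea

    @property
    def ea_kj(self) -> float:
        return self.ea / 1000.0

    def predict_k1k2(self, c: float, temperature_k):
        """(k1, k2) in days at enzyme load ``c`` (units) and T (kelvin)."""
        if not c > 0:
            raise ParameterError("enzyme concentration must be positive")
        t = np.asarray(temperature_k, dtype=float)
        x = 1.0 / t - 1.0 / self.tref_k
        k1 = self.k1ref_c1 * c ** (-self.alpha) * np.exp((self.ea / R_GAS) * x)
        k2 = self.k2ref_c1 * c ** (-self.beta) * np.exp((self.ea_k2 / R_GAS) * x)
        if k1.shape:
            return k1, k2
        return float(k1), float(k2)

    def response(self, t, c: float, temperature_k: float):
        """Normalized response at time(s) t for a label (C, T)."""
        k1, k2 = self.predict_k1k2(c, temperature_k)
        return logistic_response(t, k1, k2)

    def response_time(self, c: float, temperature_k,
                      endpoint: float = ENDPOINT_DEFAULT):
        """Days until the label reaches its visual end point (default 0.8)."""
        if not 0.0 < endpoint < 1.0:
            raise ParameterError("endpoint must lie in (0, 1)")
        k1, k2 = self.predict_k1k2(c, temperature_k)
        out = k1 + k2 * math.log(endpoint / (1.0 - endpoint))
        return out

    def summary(self) -> str:
        return (
            f"Global TTI model ({self.tti_type or '?'}-type)\n"
            f"  Ea = {self.ea_kj:.1f} kJ/mol,  "
            f"k1ref(C=1U) = {self.k1ref_c1:.1f} d,  "
            f"k2ref(C=1U) = {self.k2ref_c1:.1f} d\n"
            f"  alpha = {self.alpha:.3f},  beta = {self.beta:.3f}"
            + (f",  pooled R^2 = {self.rsquared:.3f}"
               if self.rsquared is not None else ""))

    def to_report(self) -> dict:
        return {
            "tti_type": self.tti_type,
            "Ea_kJ_per_mol": self.ea_kj,
            "k1ref_c1_d": self.k1ref_c1,
            "k2ref_c1_d": self.k2ref_c1,
            "alpha": self.alpha,
            "beta": self.beta,
            "Tref_C": self.tref_k - 273.15,
            "r_squared": self.rsquared,
        }


def fit_global_model(fits, tti_type=None, tref_k=TREF_DEFAULT_K,
                     shared_ea=True) -> TTIGlobalResults:
    """Fit the global model from (C, T_celsius, LogisticParams) records."""
    return TTIGlobalModel(fits, tti_type=tti_type, tref_k=tref_k).fit(
        shared_ea=shared_ea)


def predict_k1k2(model: TTIGlobalResults, c: float, temperature_k):
    """Functional alias for :meth:`TTIGlobalResults.predict_k1k2`."""
    return model.predict_k1k2(c, temperature_k)


def response_time(model: TTIGlobalResults, c: float, temperature_k,
                  endpoint: float = ENDPOINT_DEFAULT):
    """Functional alias for :meth:`TTIGlobalResults.response_time`."""
    return model.response_time(c, temperature_k, endpoint=endpoint)
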