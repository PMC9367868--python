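"""Non-isothermal prediction and validation.

Cold-chain temperature histories are piecewise-constant logger profiles.
Three tools live here:

* the *effective temperature* Teff of a profile — the constant temperature
  whose Arrhenius factor equals the time-average factor of the variable
  profile over the same duration;
* growth prediction under a varying profile, by integrating the
  differential Baranyi system with the temperature-dependent rate from a
  secondary model and the lag carried by the physiological state q;
* the relative-error metric RE% = |(k_exp - k_pred)/k_exp| * 100 used to
  validate predicted growth rates against observed ones (applicability
  criterion: 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .arrhenius import ArrheniusResults, R_GAS, celsius_to_kelvin
from .baranyi import LN10, BaranyiParams, BaranyiModel, BaranyiResults
from .exceptions import IntegrationError, ParameterError, ProfileError

TEMP_RANGE_C = (-5.0, 25.0)
RE_LIMIT_PCT = 20.0
_EA_DEGENERATE = 1e-6  # J/mol; below this the Arrhenius inversion is singular

__all__ = [
    "TemperatureProfile",
    "ValidationResult",
    "effective_temperature",
    "predict_growth_dynamic",
    "apparent_growth_rate",
    "relative_error",
]


@dataclass
class TemperatureProfile:
    """Piecewise-constant time-temperature history.

    ``segments`` is an ordered list of (start_d, end_d, temperature_K)
    triples, contiguous and starting at time 0.
    """

    segments: list[tuple[float, float, float]]

    def __post_init__(self):
        if not self.segments:
            raise ProfileError("profile has no segments")
        segs = [(float(a), float(b), float(t)) for a, b, t in self.segments]
        if abs(segs[0][0]) > 1e-12:
            raise ProfileError("profile must start at time 0")
        for (a1, b1, _), (a2, _, _) in zip(segs, segs[1:]):
            if abs(b1 - a2) > 1e-9:
                raise ProfileError("segments must be contiguous")
        for a, b, t in segs:
            if b <= a:
                raise ProfileError(f"segment ({a}, {b}) has non-positive duration")
            t_c = t - 273.15
            if not (TEMP_RANGE_C[0] <= t_c <= TEMP_RANGE_C[1]):
                raise ProfileError(
                    f"segment temperature {t_c:.1f} degC outside -5..25 degC")
        self.segments = segs

    @classmethod
    def constant(cls, duration_d: float, temperature_c: float):
        return cls([(0.0, float(duration_d),
                     float(celsius_to_kelvin(temperature_c)))])

    @classmethod
    def from_celsius_segments(cls, segments):
        return cls([(a, b, float(celsius_to_kelvin(t))) for a, b, t in segments])

    @property
    def total_duration(self) -> float:
        return self.segments[-1][1]

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b, _ in self.segments])

    @property
    def temperatures_k(self) -> np.ndarray:
        return np.array([t for _, _, t in self.segments])

    def temperature_at(self, t_d: float) -> float:
        """Temperature (K) at a time in days (right-continuous)."""
        if not 0.0 <= t_d <= self.total_duration:
            raise ProfileError(f"time {t_d} outside the profile")
        for a, b, temp in self.segments:
            if a <= t_d < b:
                return temp
        return self.segments[-1][2]


def effective_temperature(profile: TemperatureProfile, ea: float,
                          tref_k: float) -> float:
    """Constant temperature equivalent to the profile under Arrhenius kinetics.

    Solves exp(-(Ea/R)(1/Teff - 1/Tref)) =
    (1/D) * sum_i dur_i * exp(-(Ea/R)(1/T_i - 1/Tref)) in closed form.
    As Ea -> 0 the inversion degenerates; by convention the
    duration-weighted arithmetic mean temperature is returned.
    Teff always lies within [min T_i, max T_i] and, for Ea > 0, at or
    above the arithmetic mean (Jensen's inequality).
    """
    if ea < 0:
        raise ParameterError("Ea must be non-negative")
    dur = profile.durations
    temps = profile.temperatures_k
    if ea < _EA_DEGENERATE:
        return float(np.average(temps, weights=dur))
    x = 1.0 / temps - 1.0 / tref_k
    mean_factor = float(np.average(np.exp(-(ea / R_GAS) * x), weights=dur))
    inv_teff = 1.0 / tref_k - (R_GAS / ea) * math.log(mean_factor)
    return 1.0 / inv_teff


def predict_growth_dynamic(ref_params: BaranyiParams,
                           rate_model: ArrheniusResults,
                           profile: TemperatureProfile,
                           n_points: int = 201):
    """Log10 count trajectory under a varying temperature profile.

    Integrates the differential Baranyi system in natural-log units,

        dp/dt = mu~(T(t))                      (p = ln q, lag state)
        dy~/dt = mu~(T(t)) * expit(p) * (1 - exp(y~ - y~max)),

    segment by segment (the rate is constant within a segment), with
    q(0) = 1 / (exp(mu~(Tref) * lag) - 1) so that at the reference
    temperature the trajectory reproduces the isothermal explicit
    solution.  A zero/absent lag starts growth immediately (q0 -> inf).

    Parameters
    ----------
    ref_params : BaranyiParams
        Parameters at the rate model's reference temperature; ``mu`` is
        ignored in favor of ``rate_model.predict`` evaluated at Tref.
    rate_model : ArrheniusResults (rate_like)
    profile : TemperatureProfile
    n_points : int
        Size of the returned uniform time grid.

    Returns
    -------
    (times_d, log10_counts) : tuple of ndarray
    """
    if rate_model.direction != "rate_like":
        raise ParameterError("rate_model must be rate_like")
    mu_ref_nat = rate_model.predict(rate_model.tref_k) * LN10
    lag = 0.0 if ref_params.lag is None else ref_params.lag
    h0 = mu_ref_nat * lag
    p0 = 50.0 if h0 <= 0 else -math.log(math.expm1(h0))
    y0_nat = ref_params.y0 * LN10
    ymax_nat = ref_params.ymax * LN10

    times = np.linspace(0.0, profile.total_duration, n_points)
    out = np.empty_like(times)
    state = np.array([p0, y0_nat])
    t_done = 0.0
    for a, b, temp in profile.segments:
        mu_nat = rate_model.predict(temp) * LN10

        def rhs(t, s, mu_nat=mu_nat):
            p, y = s
            dy = mu_nat * expit(p) * -np.expm1(min(y - ymax_nat, 0.0))
            return [mu_nat, dy]

        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        t_eval = np.clip(times[mask], a, b)
        sol = solve_ivp(rhs, (a, b), state, method="DOP853",
                        t_eval=t_eval if t_eval.size else None,
                        rtol=1e-11, atol=1e-12)
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed on segment ({a}, {b}): {sol.message}")
        if t_eval.size:
            out[mask] = sol.y[1] / LN10
        state = sol.y[:, -1] if sol.y.shape[1] else state
        # re-integrate to the exact segment end for the next initial state
        if t_eval.size == 0 or abs(t_eval[-1] - b) > 1e-12:
            sol_end = solve_ivp(rhs, (a if t_eval.size == 0 else t_eval[-1], b),
                                state, method="DOP853", rtol=1e-11, atol=1e-12)
            if not sol_end.success:
                raise IntegrationError(sol_end.message)
            state = sol_end.y[:, -1]
        t_done = b
    out[0] = ref_params.y0  # exact by construction
    return times, out


def apparent_growth_rate(times, log_counts, with_lag="auto") -> BaranyiResults:
    """Exponential-phase growth rate of a (possibly model-generated) curve.

    Fits the Baranyi model and returns the full results object; the rate
    is ``result.mu``.  Used identically for observed counts and for
    trajectories produced by :func:`predict_growth_dynamic`, so observed
    and predicted rates are comparable.
    """
    return BaranyiModel(np.asarray(times, float),
                        np.asarray(log_counts, float)).fit(with_lag=with_lag)


@dataclass(frozen=True)
class ValidationResult:
    """Observed-vs-predicted rate comparison with the RE% applicability flag."""

    k_experimental: float
    k_predicted: float
    re_percent: float
    pass_20pct: bool

    @property
    def re_percent_rounded(self) -> int:
        """RE% rounded to the nearest integer percent (for report display)."""
        return int(round(self.re_percent))


def relative_error(k_experimental: float, k_predicted: float) -> ValidationResult:
    """RE% = |(k_exp - k_pred) / k_exp| * 100, with the 20% pass flag."""
    if not k_experimental > 0:
        raise ParameterError("k_experimental must be positive")
    re = abs((k_experimental - k_predicted) / k_experimental) * 100.0
    return ValidationResult(
        k_experimental=float(k_experimental), k_predicted=float(k_predicted),
        re_percent=float(re), pass_20pct=bool(re <= RE_LIMIT_PCT))
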