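"""Arrhenius secondary model for temperature dependence of growth kinetics.

Growth rates k(T) follow ln k = ln kref - (Ea/R)(1/T - 1/Tref); the slope of
ln k on reciprocal temperature gives the activation energy Ea.  Lag phases
are *time-like*: they lengthen as temperature drops, so their temperature
factor carries the opposite sign, lag(T) = lag_ref * exp(+(Ea/R)(1/T - 1/Tref)).
(Writing the rate-like sign on a lag term, as is sometimes done, would
shorten lags in colder storage, contradicting observed chill-storage data;
the package normalizes the sign and documents it.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import DesignError, ParameterError

R_GAS = 8.314  # J / (mol K)
TREF_DEFAULT_K = 277.15  # 4 degC, the chill-chain reference temperature

__all__ = [
    "R_GAS",
    "TREF_DEFAULT_K",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "RatePoint",
    "ArrheniusModel",
    "ArrheniusResults",
    "fit_arrhenius",
    "predict_rate",
    "fit_lag_reference",
]


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


@dataclass(frozen=True)
class RatePoint:
    """One temperature/value pair for secondary-model fitting.

    ``value`` is a growth rate (log10 CFU/g per day) for rate-like fits or
    a lag (days) for time-like fits; it must be positive because the model
    is linear in ln(value).
    """

    temperature_k: float
    value: float
    standard_error: float | None = None

    def __post_init__(self):
        if not self.temperature_k > 250.0:
            raise ParameterError(
                f"temperature {self.temperature_k} K implausible (must be > 250 K)")
        if not (np.isfinite(self.value) and self.value > 0):
            raise ParameterError(f"value must be positive, got {self.value}")


class ArrheniusModel:
    """Arrhenius regression of ln(value) on (1/T - 1/Tref).

    Parameters
    ----------
    points : sequence of RatePoint (or (T_K, value) tuples)
    direction : {"rate_like", "time_like"}
        Rate-like quantities increase with temperature; time-like
        quantities (lags, response times) decrease.
    tref_k : float
        Reference temperature in kelvin (default 277.15 K = 4 degC).
    weighted : bool
        When True and standard errors are available, inverse-variance
        weights on the ln scale, w_i = (value_i / se_i)^2.
    """

    def __init__(self, points, direction="rate_like", tref_k=TREF_DEFAULT_K,
                 weighted=False):
        pts = [p if isinstance(p, RatePoint) else RatePoint(*p) for p in points]
        if direction not in ("rate_like", "time_like"):
            raise ParameterError(f"unknown direction {direction!r}")
        temps = np.array([p.temperature_k for p in pts])
        if len(np.unique(temps)) < 3:
            raise DesignError("need values at >= 3 distinct temperatures")
        self.points = pts
        self.direction = direction
        self.tref_k = float(tref_k)
        self.weighted = weighted

    @classmethod
    def from_results(cls, baranyi_results, temperatures_c, **kw):
        """Build a rate-like model from Baranyi fits at several temperatures."""
        pts = [RatePoint(celsius_to_kelvin(tc).item(), r.params.mu,
                         float(r.bse[2]) if np.isfinite(r.bse[2]) else None)
               for r, tc in zip(baranyi_results, temperatures_c)]
        return cls(pts, direction="rate_like", **kw)

    def fit(self) -> "ArrheniusResults":
        temps = np.array([p.temperature_k for p in self.points])
        vals = np.array([p.value for p in self.points])
        x = 1.0 / temps - 1.0 / self.tref_k
        y = np.log(vals)
        X = sm.add_constant(x)
        if self.weighted:
            ses = [p.standard_error for p in self.points]
            if any(s is None or not s > 0 for s in ses):
                raise ParameterError("weighted fit requires positive standard errors")
            w = (vals / np.array(ses)) ** 2
            res = sm.WLS(y, X, weights=w).fit()
        else:
            res = sm.OLS(y, X).fit()
        intercept, slope = res.params
        sign = -1.0 if self.direction == "rate_like" else 1.0
        ea = sign * R_GAS * slope
        ea_se = R_GAS * res.bse[1]
        # a flat line (all values equal) has zero total variation; call it
        # a perfect fit rather than dividing by zero
        rsq = 1.0 if np.ptp(y) == 0 else float(res.rsquared)
        return ArrheniusResults(
            kref=math.exp(intercept), ea=float(ea),
            direction=self.direction, tref_k=self.tref_k,
            kref_se=math.exp(intercept) * float(res.bse[0]), ea_se=float(ea_se),
            rsquared=rsq, nobs=len(self.points), model=self)


@dataclass
class ArrheniusResults:
    """Secondary model: value(T) = kref * exp(-+(Ea/R)(1/T - 1/Tref)).

    ``ea`` is in J/mol; ``kref`` is the value at the reference temperature.
    The sign of the exponent follows ``direction``.  Usually produced by
    :meth:`ArrheniusModel.fit`, but may be built directly from published
    constants (``model`` then stays None).
    """

    kref: float
    ea: float
    direction: str = "rate_like"
    tref_k: float = TREF_DEFAULT_K
    kref_se: float = float("nan")
    ea_se: float = float("nan")
    rsquared: float | None = None
    nobs: int | None = None
    model: ArrheniusModel | None = None

    def __post_init__(self):
        if self.direction not in ("rate_like", "time_like"):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if self.ea < 0:
            raise ParameterError("Ea must be non-negative")
        if not self.kref > 0:
            raise ParameterError("kref must be positive")

    @property
    def ea_kj(self) -> float:
        return self.ea / 1000.0

    def predict(self, temperature_k):
        """Value of the modeled quantity at temperature(s) in kelvin."""
        t = np.asarray(temperature_k, dtype=float)
        x = 1.0 / t - 1.0 / self.tref_k
        sign = -1.0 if self.direction == "rate_like" else 1.0
        out = self.kref * np.exp(sign * (self.ea / R_GAS) * x)
        return out if out.shape else float(out)

    def summary(self) -> str:
        return (
            "Arrhenius secondary model\n"
            f"  direction = {self.direction},  Tref = "
            f"{kelvin_to_celsius(self.tref_k):.2f} degC\n"
            f"  kref = {self.kref:.4g}  (se {self.kref_se:.2g})\n"
            f"  Ea   = {self.ea_kj:.1f} kJ/mol  (se {self.ea_se / 1000:.1f})\n"
            + (f"  R^2  = {self.rsquared:.3f}  on {self.nobs} points"
               if self.rsquared is not None else "  (published constants)"))

    def to_report(self) -> dict:
        """JSON-ready fit report."""
        return {
            "kref": self.kref,
            "Ea_kJ_per_mol": self.ea_kj,
            "Tref_C": float(kelvin_to_celsius(self.tref_k)),
            "r_squared": self.rsquared,
            "direction": self.direction,
        }

    @classmethod
    def from_constants(cls, kref: float, ea_kj: float, tref_c: float = 4.0,
                       direction: str = "rate_like") -> "ArrheniusResults":
        """Build from published constants (kref in the quantity's units,
        Ea in kJ/mol, Tref in degC)."""
        return cls(kref=kref, ea=ea_kj * 1000.0, direction=direction,
                   tref_k=float(celsius_to_kelvin(tref_c)))


def fit_arrhenius(points, tref_k=TREF_DEFAULT_K, direction="rate_like",
                  weighted=False) -> ArrheniusResults:
    """Functional wrapper around :class:`ArrheniusModel` (see its docs)."""
    return ArrheniusModel(points, direction=direction, tref_k=tref_k,
                          weighted=weighted).fit()


def predict_rate(fit: ArrheniusResults, temperature_k):
    """Evaluate a fitted secondary model at the given temperature(s) (K)."""
    return fit.predict(temperature_k)


def fit_lag_reference(lag_points, ea: float, tref_k=TREF_DEFAULT_K):
    """Reference lag lambda_ref (days) sharing Ea with the rate model.

    Uses the geometric-mean estimator with the time-like temperature
    scaling: lambda_ref = exp(mean_i[ln lambda_i - (Ea/R)(1/T_i - 1/Tref)]).
    Points with missing or zero lag are ignored; if none remain, returns
    (0.0, flag=True) meaning the no-lag variant applies throughout.

    Returns
    -------
    (lag_ref, all_absent) : tuple of (float, bool)
    """
    pts = [p if isinstance(p, RatePoint) else p for p in lag_points]
    usable = []
    for p in pts:
        if isinstance(p, RatePoint):
            usable.append((p.temperature_k, p.value))
        else:
            t, v = p
            if v is not None and v > 0:
                usable.append((float(t), float(v)))
    if not usable:
        return 0.0, True
    temps = np.array([t for t, _ in usable])
    lags = np.array([v for _, v in usable])
    x = 1.0 / temps - 1.0 / tref_k
    return float(np.exp(np.mean(np.log(lags) - (ea / R_GAS) * x))), False
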