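"""Baranyi-Roberts primary growth model.

The model describes a bacterial count curve on the log10 scale with four
parameters: the initial level ``y0``, the carrying capacity ``ymax``, the
maximum growth rate ``mu`` (log10 CFU/g per day) and an optional lag phase
``lag`` (days).  Internally the explicit solution is evaluated in natural-log
concentration units,

    y~(t) = y~0 + mu~ A(t) - ln(1 + (exp(mu~ A(t)) - 1) / exp(y~max - y~0))

with the adjustment function

    A(t) = t + (1/mu~) ln(exp(-mu~ t) + exp(-h0) - exp(-mu~ t - h0)),

where ``h0 = mu~ * lag`` encodes the physiological state of the inoculum,
``mu~ = mu ln10`` and ``y~ = y ln10``.  The curvature parameter is fixed at
m = 1 and the transition rate at nu = mu_max, the convention used by DMfit.

A statsmodels-style interface is provided: build a :class:`BaranyiModel`
from a time/log-count series and call :meth:`~BaranyiModel.fit` to obtain a
:class:`BaranyiResults` with estimates, standard errors, R^2 and residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    FittingError,
    NoGrowthError,
    ParameterError,
    UnreachableThresholdError,
)

LN10 = math.log(10.0)

ORGANISMS = ("TVC", "Pseudomonas", "Enterobacteriaceae", "H2S_producers")
PACKAGINGS = ("MAP", "MAP_PAD")

__all__ = [
    "BaranyiParams",
    "GrowthCurve",
    "BaranyiModel",
    "BaranyiResults",
    "baranyi_log_count",
    "fit_baranyi",
    "time_to_threshold",
]


@dataclass(frozen=True)
class BaranyiParams:
    """Parameters of the Baranyi-Roberts model on the log10 scale.

    Parameters
    ----------
    y0 : float
        Initial log10 count (log10 CFU/g).
    ymax : float
        Final (stationary-phase) log10 count; must exceed ``y0``.
    mu : float
        Maximum growth rate, log10 CFU/g per day; must be positive.
    lag : float or None
        Lag phase in days.  ``None`` selects the no-lag model variant
        (growth starts immediately); 0.0 is equivalent.
    """

    y0: float
    ymax: float
    mu: float
    lag: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.y0) and np.isfinite(self.ymax)):
            raise ParameterError("y0 and ymax must be finite")
        if self.y0 >= self.ymax:
            raise ParameterError(f"y0 ({self.y0}) must be < ymax ({self.ymax})")
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ParameterError(f"mu must be positive, got {self.mu}")
        if self.lag is not None and (not np.isfinite(self.lag) or self.lag < 0):
            raise ParameterError(f"lag must be >= 0, got {self.lag}")

    @property
    def h0(self) -> float:
        """Physiological-state product h0 = mu~ * lag (natural-log units)."""
        lag = 0.0 if self.lag is None else self.lag
        return self.mu * LN10 * lag

    def as_array(self) -> np.ndarray:
        lag = 0.0 if self.lag is None else self.lag
        return np.array([self.y0, self.ymax, self.mu, lag])


@dataclass
class GrowthCurve:
    """One observed log10 count series for an organism/packaging/temperature.

    ``times`` must be strictly increasing and non-negative.  At least four
    observations are required to fit the model with a lag phase, three
    without.
    """

    times: np.ndarray
    log_counts: np.ndarray
    organism: str | None = None
    packaging: str | None = None
    temperature_c: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.log_counts = np.asarray(self.log_counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.log_counts.shape:
            raise ParameterError("times and log_counts must be matching 1-d arrays")
        if self.times.size and self.times[0] < 0:
            raise ParameterError("times must be non-negative")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.log_counts)):
            raise ParameterError("observations must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.organism is not None and self.organism not in ORGANISMS:
            raise ParameterError(f"unknown organism {self.organism!r}")
        if self.packaging is not None and self.packaging not in PACKAGINGS:
            raise ParameterError(f"unknown packaging {self.packaging!r}")

    def __len__(self):
        return self.times.size


def _log_adjustment(t: np.ndarray, mu_nat: float, h0: float) -> np.ndarray:
    """Adjustment function A(t) of the Baranyi model, natural-log units.

    Evaluated as A(t) = t + (1/mu~) ln(exp(-mu~ t)(1 - exp(-h0)) + exp(-h0)),
    a rearrangement whose two summands are both positive, so it is safe in
    log space for any h0 >= 0.
    """
    if h0 <= 0.0:
        return t
    # ln(1 - e^{-h0}) without cancellation
    log1m = math.log(-math.expm1(-h0))
    inner = np.logaddexp(-mu_nat * t + log1m, -h0)
    return t + inner / mu_nat


def baranyi_log_count(t, params: BaranyiParams):
    """Evaluate the explicit Baranyi-Roberts solution.

    Parameters
    ----------
    t : array_like
        Time(s) in days, >= 0.
    params : BaranyiParams

    Returns
    -------
    ndarray or float
        log10 CFU/g at each requested time.  ``y(0) == y0`` exactly and
        ``y(t) -> ymax`` as ``t -> inf``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("t must be >= 0")
    mu_nat = params.mu * LN10
    a = _log_adjustment(t_arr, mu_nat, params.h0)
    x = mu_nat * a                      # growth accrued, natural log units
    d = (params.ymax - params.y0) * LN10
    # ln(1 + (e^x - 1) e^{-d}) = ln(e^{x-d} + (1 - e^{-d})), both terms > 0
    brake = np.logaddexp(x - d, math.log(-math.expm1(-d)))
    y = params.y0 + (x - brake) / LN10
    return y if y.shape else float(y)


def time_to_threshold(params: BaranyiParams, threshold: float) -> float:
    """Time (days) at which the modeled count first reaches ``threshold``.

    Solved by bracketed root finding on the explicit solution to better
    than 1e-9 days.  A threshold at or below ``y0`` returns 0.0 with a
    warning; a threshold above ``ymax`` is unreachable; a threshold equal
    to ``ymax`` returns ``inf``.
    """
    if threshold > params.ymax:
        raise UnreachableThresholdError(
            f"threshold {threshold} exceeds ymax {params.ymax}"
        )
    if threshold <= params.y0:
        warnings.warn("threshold at or below initial level; returning 0.0",
                      stacklevel=2)
        return 0.0
    if threshold == params.ymax:
        return math.inf

    def f(t):
        return baranyi_log_count(t, params) - threshold

    # expand the bracket geometrically from a scale set by the parameters
    lag = 0.0 if params.lag is None else params.lag
    hi = max(1.0, lag + (threshold - params.y0) / params.mu)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            raise UnreachableThresholdError("threshold not reached numerically")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def _residual_factory(times, log_counts, with_lag):
    if with_lag:
        def resid(theta):
            y0, ymax, mu, lag = theta
            p = BaranyiParams(y0=y0, ymax=ymax, mu=mu, lag=lag)
            return baranyi_log_count(times, p) - log_counts
    else:
        def resid(theta):
            y0, ymax, mu = theta
            p = BaranyiParams(y0=y0, ymax=ymax, mu=mu, lag=None)
            return baranyi_log_count(times, p) - log_counts
    return resid


class BaranyiModel:
    """Baranyi-Roberts growth model bound to one observed curve.

    Parameters
    ----------
    times, log_counts : array_like
        The observed series (days, log10 CFU/g), or pass a
        :class:`GrowthCurve` to :meth:`from_curve` /
        a tidy frame to :meth:`from_dataframe`.
    """

    def __init__(self, times, log_counts, *, organism=None, packaging=None,
                 temperature_c=None):
        self.curve = GrowthCurve(times, log_counts, organism=organism,
                                 packaging=packaging, temperature_c=temperature_c)

    @classmethod
    def from_curve(cls, curve: GrowthCurve) -> "BaranyiModel":
        m = cls.__new__(cls)
        m.curve = curve
        return m

    @classmethod
    def from_dataframe(cls, df, *, time_col="time_d", count_col="log10_count"):
        """Build from a tidy frame with time and log10-count columns.

        Replicate rows at the same time are averaged before fitting.
        """
        g = df.groupby(time_col, sort=True)[count_col].mean()
        meta = {}
        for attr, col in [("organism", "organism"), ("packaging", "packaging"),
                          ("temperature_c", "temperature_C")]:
            if col in df.columns:
                vals = df[col].unique()
                if len(vals) != 1:
                    raise ParameterError(
                        f"from_dataframe expects a single {col}, got {list(vals)}")
                meta[attr] = vals[0]
        return cls(g.index.to_numpy(float), g.to_numpy(float), **meta)

    # -- initial values per the package's initialization rule ---------------
    def _start(self, with_lag):
        t, y = self.curve.times, self.curve.log_counts
        y0 = y[0]
        ymax = y.max()
        slopes = np.diff(y) / np.diff(t)
        mu = max(float(slopes.max()), 1e-3)
        x0 = [y0, max(ymax, y0 + 0.5), min(mu, 10.0)]
        lo = [y0 - 2.0, ymax - 0.2, 1e-6]
        hi = [y0 + 2.0, ymax + 2.0, 10.0]
        if with_lag:
            above = np.nonzero(y > y0 + 0.2)[0]
            lag0 = float(t[above[0]]) if above.size else 0.0
            x0.append(min(lag0, t[-1]))
            lo.append(0.0)
            hi.append(float(t[-1]))
        # keep the start strictly inside the box
        x0 = np.clip(x0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        return np.asarray(x0), (np.asarray(lo), np.asarray(hi))

    def _fit_variant(self, with_lag):
        t, y = self.curve.times, self.curve.log_counts
        resid = _residual_factory(t, y, with_lag)
        x0, bounds = self._start(with_lag)
        best = None
        for shift in (0.0, 0.3, -0.3):
            start = np.clip(x0 * (1 + shift) + (0.1 * shift if with_lag else 0),
                            bounds[0] + 1e-9, bounds[1] - 1e-9)
            try:
                sol = optimize.least_squares(resid, start, bounds=bounds,
                                             xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (ValueError, ParameterError):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FittingError("Baranyi fit did not converge",
                               incumbent=None if best is None else best.x)
        return best

    def fit(self, with_lag="auto") -> "BaranyiResults":
        """Least-squares fit of the model on the log10 scale.

        Parameters
        ----------
        with_lag : {"auto", True, False}
            "auto" fits both variants and keeps the lag only when an
            F-test at alpha = 0.05 finds it significant, mirroring the
            practice of dropping a non-significant lag phase.  A lag
            estimate pinned at the zero bound also falls back to the
            no-lag variant (flagged on the result).

        Raises
        ------
        NoGrowthError
            If the series never rises more than 0.2 log10 above its
            first observation (flat or decreasing curve).
        DesignError-like ParameterError
            If there are fewer observations than parameters.
        """
        t, y = self.curve.times, self.curve.log_counts
        n = t.size
        want_lag = with_lag in (True, "auto")
        if n < (4 if with_lag is True else 3):
            raise ParameterError(
                f"need >= {4 if with_lag is True else 3} observations, got {n}")
        if y[1:].size == 0 or (y[1:].max() - y[0]) < 0.2:
            raise NoGrowthError("series shows no growth above the initial level")

        sol_nolag = self._fit_variant(False)
        ss_nolag = 2 * sol_nolag.cost
        chosen, lag_dropped = None, False

        if want_lag and n >= 4:
            sol_lag = self._fit_variant(True)
            ss_lag = 2 * sol_lag.cost
            lag_est = sol_lag.x[3]
            if with_lag == "auto":
                df2 = n - 4
                keep = False
                if df2 > 0 and ss_lag < ss_nolag and lag_est > 1e-6:
                    fstat = (ss_nolag - ss_lag) / (ss_lag / df2)
                    keep = stats.f.sf(fstat, 1, df2) < 0.05
                if keep:
                    chosen = (sol_lag, True)
                else:
                    chosen, lag_dropped = (sol_nolag, False), lag_est <= 1e-6
            else:  # with_lag is True
                if lag_est <= 1e-6:
                    chosen, lag_dropped = (sol_nolag, False), True
                else:
                    chosen = (sol_lag, True)
        if chosen is None:
            chosen = (sol_nolag, False)

        sol, has_lag = chosen
        theta = sol.x
        params = BaranyiParams(
            y0=theta[0], ymax=theta[1], mu=theta[2],
            lag=float(theta[3]) if has_lag else None)

        res = baranyi_log_count(t, params) - y
        ss_res = float(res @ res)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

        p = 4 if has_lag else 3
        dof = max(n - p, 1)
        s2 = ss_res / dof
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * s2
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = np.full(p, np.nan)

        return BaranyiResults(
            model=self, params=params, bse=bse, cov_params=cov,
            rsquared=r2, resid=-res, nobs=n, lag_dropped=lag_dropped)


@dataclass
class BaranyiResults:
    """Fit results for :class:`BaranyiModel`.

    Attributes
    ----------
    params : BaranyiParams
    bse : ndarray
        Standard errors for (y0, ymax, mu[, lag]).
    rsquared : float
        1 - SSres/SStot on log10 counts.
    resid : ndarray
        Observed minus fitted, log10 CFU/g.
    lag_dropped : bool
        True when a requested lag hit the zero bound (or was not
        significant) and the no-lag variant was reported instead.
    """

    model: BaranyiModel
    params: BaranyiParams
    bse: np.ndarray
    cov_params: np.ndarray
    rsquared: float
    resid: np.ndarray
    nobs: int
    lag_dropped: bool = False
    param_names: Sequence[str] = field(init=False)

    def __post_init__(self):
        self.param_names = (
            ("y0", "ymax", "mu", "lag") if self.params.lag is not None
            else ("y0", "ymax", "mu"))

    def predict(self, t):
        """Fitted log10 count at time(s) ``t`` (days)."""
        return baranyi_log_count(t, self.params)

    def time_to_threshold(self, threshold: float) -> float:
        return time_to_threshold(self.params, threshold)

    @property
    def mu(self) -> float:
        return self.params.mu

    @property
    def lag(self) -> float | None:
        return self.params.lag

    def summary(self) -> str:
        c = self.model.curve
        head = ["Baranyi-Roberts growth model"]
        if c.organism or c.packaging or c.temperature_c is not None:
            head.append(
                f"  {c.organism or '?'} / {c.packaging or '?'} @ "
                f"{c.temperature_c if c.temperature_c is not None else '?'} degC")
        head.append(f"  nobs = {self.nobs},  R^2 = {self.rsquared:.4f}"
                    + ("  [lag dropped]" if self.lag_dropped else ""))
        rows = [f"  {name:>5s} = {val:10.4f}  (se {se:.4f})"
                for name, val, se in zip(
                    self.param_names,
                    self.params.as_array()[:len(self.param_names)],
                    self.bse)]
        return "\n".join(head + rows)


def fit_baranyi(curve: GrowthCurve, with_lag="auto") -> BaranyiResults:
    """Functional wrapper: fit a :class:`GrowthCurve` (see BaranyiModel.fit)."""
    return BaranyiModel.from_curve(curve).fit(with_lag=with_lag)
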