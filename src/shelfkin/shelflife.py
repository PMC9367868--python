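"""Shelf-life estimation from secondary-model kinetics.

The shelf life at temperature T is the time for the total viable count to
grow from the initial load logN0 to the acceptability limit logN1 (default
7 log10 CFU/g for chilled fish), plus the lag phase:

    t_SL(T) = (logN1 - logN0) / k(T) + lag_ref * exp(+(Ea/R)(1/T - 1/Tref))

with k(T) from a rate-like Arrhenius fit and the lag scaled with the
time-like sign so that shelf life is strictly decreasing in temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .arrhenius import ArrheniusResults, R_GAS, kelvin_to_celsius
from .exceptions import ParameterError

CAL_RANGE_C = (0.0, 10.0)     # temperatures spanned by the kinetic study
HARD_RANGE_C = (-5.0, 25.0)   # beyond this, refuse to extrapolate

__all__ = ["ShelfLifeSpec", "estimate_shelf_life", "shelf_life_curve"]


@dataclass
class ShelfLifeSpec:
    """Everything needed to predict shelf life at any temperature.

    Parameters
    ----------
    log_n0, log_n1 : float
        Initial microbial load and acceptability limit, log10 CFU/g.
    rate_model : ArrheniusResults
        Rate-like secondary model of the TVC growth rate.
    lag_ref : float
        Reference lag (days) at the rate model's Tref; 0 disables the
        lag term.
    ea_shared : float or None
        Activation energy (J/mol) used for the lag term; defaults to the
        rate model's Ea (a single Ea shared by rate and lag).
    """

    rate_model: ArrheniusResults
    log_n0: float
    log_n1: float = 7.0
    lag_ref: float = 0.0
    ea_shared: float | None = None
    label: str | None = None
    extrapolated: bool = field(default=False, init=False)

    def __post_init__(self):
        if not self.log_n1 > self.log_n0:
            raise ParameterError("log_n1 must exceed log_n0")
        if self.rate_model.direction != "rate_like":
            raise ParameterError("rate_model must be a rate_like fit")
        if not self.rate_model.kref > 0:
            raise ParameterError("rate_model.kref must be positive")
        if self.lag_ref < 0:
            raise ParameterError("lag_ref must be >= 0")
        if self.ea_shared is None:
            self.ea_shared = self.rate_model.ea

    @property
    def ea(self) -> float:
        """Activation energy (J/mol) of the product's deterioration rate."""
        return self.rate_model.ea


def estimate_shelf_life(spec: ShelfLifeSpec, temperature_k: float) -> float:
    """Predicted shelf life in days at a constant temperature (K).

    Temperatures outside the 0-10 degC calibration range trigger an
    extrapolation warning (and set ``spec.extrapolated``); temperatures
    outside -5..25 degC raise a range error.
    """
    t_c = float(kelvin_to_celsius(temperature_k))
    if not (HARD_RANGE_C[0] <= t_c <= HARD_RANGE_C[1]):
        raise ParameterError(
            f"temperature {t_c:.1f} degC far outside the model's validity range")
    if not (CAL_RANGE_C[0] <= t_c <= CAL_RANGE_C[1]):
        spec.extrapolated = True
        warnings.warn(
            f"temperature {t_c:.1f} degC is outside the 0-10 degC calibration "
            "range; shelf-life value is an extrapolation", stacklevel=2)
    rate = spec.rate_model.predict(temperature_k)
    x = 1.0 / float(temperature_k) - 1.0 / spec.rate_model.tref_k
    lag = spec.lag_ref * np.exp((spec.ea_shared / R_GAS) * x)
    return float((spec.log_n1 - spec.log_n0) / rate + lag)


def shelf_life_curve(spec: ShelfLifeSpec, temperatures_k) -> np.ndarray:
    """Shelf life (days) along a sorted temperature grid (K).

    Returns an array of shape (n, 2) with columns (T_K, days), preserving
    the grid order.
    """
    grid = np.atleast_1d(np.asarray(temperatures_k, dtype=float))
    if grid.size == 0:
        raise ParameterError("temperature grid must be non-empty")
    days = np.array([estimate_shelf_life(spec, t) for t in grid])
    return np.column_stack([grid, days])
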