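"""Seeded synthetic data with the statistical structure the models assume.

The generators emulate the chill-storage study design: log10 plate counts
that follow Baranyi-shaped curves with additive Gaussian noise on the log
scale, sigmoidal TTI color responses with additive noise on the normalized
response, and piecewise-constant cold-chain temperature profiles in
0-10 degC (the validation scenario uses an effective temperature of
4.8 degC).  Every generator is a pure function of its parameters and seed.

Defaults mirror the study conditions: two packagings, four organisms,
isothermal storage at 0/2.5/5/10 degC with ~10-12 sampling times over
0-25 days and plate-count noise of 0.15 log10 CFU/g; TTI labels at five
temperatures (0-15 degC) with response noise of 0.03 normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .baranyi import BaranyiParams, GrowthCurve, baranyi_log_count
from .dynamic import TemperatureProfile, effective_temperature
from .exceptions import FeasibilityError, ParameterError
from .tti import ColorReading, TTISeries, logistic_response

__all__ = [
    "StudyDesign",
    "gen_growth_curve",
    "gen_tti_series",
    "gen_temperature_profile",
    "gen_counts_table",
]

NOISE_SD_LOG10 = 0.15
TTI_NOISE_SD = 0.03


@dataclass
class StudyDesign:
    """The synthetic study layout (defaults reproduce the chill study)."""

    packagings: tuple = ("MAP", "MAP_PAD")
    organisms: tuple = ("TVC",)
    temperatures_c: tuple = (0.0, 2.5, 5.0, 10.0)
    sampling_times_d: tuple = tuple(np.linspace(0.0, 25.0, 12))
    noise_sd_log10: float = NOISE_SD_LOG10
    tti_types: tuple = ("M", "LP")
    tti_concentrations: dict = field(default_factory=lambda: {
        "M": (5, 10, 15, 20, 25, 50, 75, 100),
        "LP": (100, 150, 300, 500)})
    tti_temperatures_c: tuple = (0.0, 2.5, 5.0, 10.0, 15.0)
    tti_noise_sd: float = TTI_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_log10 < 0 or self.tti_noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def gen_growth_curve(params: BaranyiParams, times, noise_sd: float, seed,
                     **meta) -> GrowthCurve:
    """Baranyi curve sampled at ``times`` with iid Gaussian log10 noise."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    y = baranyi_log_count(t, params)
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, size=t.shape)
    return GrowthCurve(t, y, **meta)


def gen_tti_series(params, ab_min: float, ab_max: float, times,
                   noise_sd: float, seed, tti_type=None, enzyme_units=None,
                   temperature_c=None) -> TTISeries:
    """Raw (a+b)-consistent color readings from a logistic response.

    The normalized logistic response (plus optional Gaussian noise,
    clipped to [0, 1]) is mapped back through the min-max calibration to
    an (a+b) sum, split evenly between the a and b coordinates.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    norm = logistic_response(t, params.k1, params.k2)
    if noise_sd > 0:
        norm = np.clip(norm + _rng(seed).normal(0.0, noise_sd, size=t.shape),
                       0.0, 1.0)
    ab = ab_min + norm * (ab_max - ab_min)
    readings = [ColorReading(time_d=ti, a=s / 2.0, b=s / 2.0)
                for ti, s in zip(t, ab)]
    return TTISeries(readings=readings, tti_type=tti_type,
                     enzyme_units=enzyme_units, temperature_c=temperature_c,
                     ab_min=ab_min, ab_max=ab_max)


def gen_temperature_profile(kind: str, *, low_c=2.0, high_c=10.0,
                            period_d=2.0, duration_d=14.0, levels_c=None,
                            constant_c=4.8, target_teff_c=None,
                            ea=None, tref_k=None) -> TemperatureProfile:
    """Cold-chain style profile, optionally tuned to a target Teff.

    Parameters
    ----------
    kind : {"constant", "square_wave", "staircase"}
    low_c, high_c : float
        The two levels of a square wave (degC).
    period_d, duration_d : float
        Cycle length and total duration (days).
    levels_c : sequence, optional
        Temperatures of a staircase (equal dwell), degC.
    target_teff_c : float, optional
        When given (square_wave only), the within-cycle dwell fraction of
        the high level is found by bisection so that
        :func:`effective_temperature` hits the target within 0.01 degC.
        Requires ``ea`` and ``tref_k``.
    """
    if kind == "constant":
        return TemperatureProfile.constant(duration_d, constant_c)

    if kind == "staircase":
        if not levels_c:
            raise ParameterError("staircase needs levels_c")
        dwell = duration_d / len(levels_c)
        segs = [(i * dwell, (i + 1) * dwell, t) for i, t in enumerate(levels_c)]
        return TemperatureProfile.from_celsius_segments(segs)

    if kind != "square_wave":
        raise ParameterError(f"unknown profile kind {kind!r}")

    def build(frac_high):
        segs = []
        t = 0.0
        while t < duration_d - 1e-9:
            cyc = min(period_d, duration_d - t)
            th = cyc * frac_high
            if th > 1e-9:
                segs.append((t, t + th, high_c))
            if cyc - th > 1e-9:
                segs.append((t + th, t + cyc, low_c))
            t += cyc
        return TemperatureProfile.from_celsius_segments(segs)

    if target_teff_c is None:
        return build(0.5)

    if ea is None or tref_k is None:
        raise ParameterError("target_teff_c requires ea and tref_k")
    if not (min(low_c, high_c) < target_teff_c < max(low_c, high_c)):
        raise FeasibilityError(
            f"target Teff {target_teff_c} degC outside the profile's "
            f"{min(low_c, high_c)}-{max(low_c, high_c)} degC span")

    def gap(frac):
        teff_k = effective_temperature(build(frac), ea, tref_k)
        return (teff_k - 273.15) - target_teff_c

    frac = optimize.brentq(gap, 1e-6, 1 - 1e-6, xtol=1e-10)
    prof = build(frac)
    achieved = effective_temperature(prof, ea, tref_k) - 273.15
    assert abs(achieved - target_teff_c) < 0.01
    return prof


def gen_counts_table(design: StudyDesign, params_by_condition) -> pd.DataFrame:
    """Full synthetic count table in the package's CSV schema.

    ``params_by_condition`` maps (organism, packaging, temperature_c) to
    :class:`BaranyiParams`.  Seeds are derived deterministically from the
    design seed and the condition, so each curve is reproducible on its
    own.
    """
    root = np.random.default_rng(design.seed)
    rows = []
    for (org, pack, t_c), params in sorted(params_by_condition.items()):
        curve = gen_growth_curve(params, design.sampling_times_d,
                                 design.noise_sd_log10, root.spawn(1)[0])
        for t, y in zip(curve.times, curve.log_counts):
            rows.append({"organism": org, "packaging": pack,
                         "temperature_C": t_c, "time_d": t,
                         "log10_count": y, "replicate": 1})
    return pd.DataFrame(rows)
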