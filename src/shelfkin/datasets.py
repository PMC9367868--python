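"""Reference kinetic parameters for chilled gilthead seabream fillets.

These tables carry the published kinetic constants of a chill-storage study
of seabream fillets packed under modified atmosphere (20% CO2 / 60% N2 /
20% O2), with (``MAP_PAD``) and without (``MAP``) a CO2-emitter pad:
Baranyi growth parameters per organism x packaging x temperature, Arrhenius
activation energies, observed shelf lives, logistic response constants for
two enzymatic TTI chemistries (M-type, 5-100 enzyme units; LP-type,
100-500 units) at 0-15 degC, the fitted global TTI models, and the
growth rates measured and predicted in a non-isothermal validation trial
at an effective temperature of 4.8 degC.

They serve as worked inputs and cross-checks for the fitting routines; no
raw count or color curves are included (none were published).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrhenius import (
    ArrheniusResults,
    R_GAS,
    TREF_DEFAULT_K,
    fit_lag_reference,
)
from .shelflife import ShelfLifeSpec
from .tti import TTIGlobalResults

__all__ = [
    "growth_parameters",
    "activation_energies",
    "observed_shelf_life",
    "tti_rate_constants",
    "tti_global_models",
    "dynamic_observed_rates",
    "dynamic_predicted_rates",
    "reference_shelf_spec",
    "INITIAL_TVC_LOG10",
]

# Representative initial total-viable-count load of the fresh fillets,
# log10 CFU/g (batch initial loads ranged 4.5-5.4).
INITIAL_TVC_LOG10 = 5.0

_TEMPS_C = (0.0, 2.5, 5.0, 10.0)

# organism -> packaging -> (rates, rate SEs, lags (None = no lag), lag SEs, Nmax, R2)
_GROWTH = {
    "TVC": {
        "MAP_PAD": ([0.224, 0.294, 0.51, 1.07], [0.027, 0.020, 0.14, 0.23],
                    [8.44, 2.88, 3.65, 1.16], [0.97, 0.37, 0.58, 0.45],
                    [8.09, 8.48, 8.48, 8.73], [0.992, 0.982, 0.960, 0.963]),
        "MAP": ([0.186, 0.298, 0.838, 1.26], [0.031, 0.052, 0.19, 0.187],
                [6.36, 1.52, 3.88, 1.55], [1.52, 0.78, 0.56, 0.25],
                [8.14, 7.92, 8.61, 8.71], [0.953, 0.903, 0.982, 0.989]),
    },
    "Pseudomonas": {
        "MAP_PAD": ([0.130, 0.257, 0.427, 0.629], [0.016, 0.0247, 0.037, 0.035],
                    [8.76, 5.11, 4.63, 1.09], [0.13, 0.99, 0.18, 0.03],
                    [6.83, 5.71, 6.62, 6.86], [0.957, 0.771, 0.985, 0.947]),
        "MAP": ([0.143, 0.215, 0.416, 0.645], [0.032, 0.1232, 0.088, 0.221],
                [6.43, 5.20, 5.94, 0.87], [1.84, 0.34, 0.35, 0.03],
                [7.04, 6.35, 6.85, 7.50], [0.914, 0.843, 0.929, 0.916]),
    },
    "Enterobacteriaceae": {
        "MAP_PAD": ([0.251, 0.421, 0.543, 0.894], [0.073, 0.007, 0.377, 0.034],
                    [12.68, 7.12, 5.82, 1.34], [2.68, 0.80, 0.76, 0.08],
                    [6.78, 4.74, 7.23, 7.53], [0.866, 0.999, 0.982, 0.999]),
        "MAP": ([0.324, 0.433, 0.672, 1.050], [0.072, 0.033, 0.086, 0.090],
                [11.58, 4.76, 4.06, None], [1.68, 0.74, 0.9, None],
                [6.95, 4.75, 6.81, 7.60], [0.933, 0.980, 0.984, 0.812]),
    },
    "H2S_producers": {
        "MAP_PAD": ([0.183, 0.219, 0.339, 1.050], [0.041, 0.029, 0.130, 0.130],
                    [1.33, None, None, None], [0.04, None, None, None],
                    [7.95, 6.94, 7.53, 7.78], [0.888, 0.967, 0.798, 0.969]),
        "MAP": ([0.209, 0.295, 0.695, 1.150], [0.032, 0.043, 0.169, 0.160],
                [None, None, None, None], [None, None, None, None],
                [8.42, 6.69, 7.43, 8.13], [0.922, 0.931, 0.908, 0.964]),
    },
}


def growth_parameters() -> pd.DataFrame:
    """Baranyi parameters per organism x packaging x storage temperature.

    Columns: organism, packaging, temperature_C, k (log10 CFU/g/d), k_se,
    lag_d (NaN where the no-lag variant applied), lag_se, nmax, r_squared.
    """
    rows = []
    for org, packs in _GROWTH.items():
        for pack, (ks, kse, lags, lagse, nmax, r2) in packs.items():
            for i, t_c in enumerate(_TEMPS_C):
                rows.append({
                    "organism": org, "packaging": pack, "temperature_C": t_c,
                    "k": ks[i], "k_se": kse[i],
                    "lag_d": np.nan if lags[i] is None else lags[i],
                    "lag_se": np.nan if lagse[i] is None else lagse[i],
                    "nmax": nmax[i], "r_squared": r2[i]})
    return pd.DataFrame(rows)


def activation_energies() -> pd.DataFrame:
    """Published growth-rate activation energies (kJ/mol) with fit R^2."""
    rows = [
        ("TVC", "MAP_PAD", 113.1, 0.887), ("TVC", "MAP", 133.9, 0.883),
        ("Pseudomonas", "MAP_PAD", 93.7, 0.918), ("Pseudomonas", "MAP", 100.5, 0.952),
        ("Enterobacteriaceae", "MAP_PAD", 81.4, 0.969),
        ("Enterobacteriaceae", "MAP", 90.3, 0.982),
        ("H2S_producers", "MAP_PAD", 116.2, 0.961),
        ("H2S_producers", "MAP", 120.4, 0.943),
    ]
    return pd.DataFrame(rows, columns=["organism", "packaging",
                                       "ea_kj_per_mol", "r_squared"])


def observed_shelf_life() -> pd.DataFrame:
    """Observed shelf life (days to 7 log10 CFU/g TVC) per packaging/temp."""
    rows = [(0.0, 17, 16), (2.5, 13, 11), (5.0, 8, 6), (10.0, 3, 3)]
    return pd.DataFrame(rows, columns=["temperature_C", "MAP_PAD", "MAP"])


_TTI_TEMPS_C = (0.0, 2.5, 5.0, 10.0, 15.0)

# tti_type -> C -> (k1 list, k1 se, k2 list, k2 se) over _TTI_TEMPS_C
_TTI = {
    "M": {
        5: ([50.4, 37.2, 29.2, 10.2, 6.90], [1.91, 1.24, 0.43, 0.32, 0.02],
            [7.83, 4.07, 3.20, 1.48, 1.24], [1.60, 0.94, 0.31, 0.26, 0.02]),
        10: ([31.3, 23.1, 14.0, 6.85, 3.97], [0.36, 0.10, 0.37, 0.02, 0.04],
             [6.18, 2.37, 3.65, 0.57, 0.59], [0.44, 0.09, 0.35, 0.02, 0.04]),
        15: ([22.3, 18.1, 12.3, 5.57, 3.11], [0.36, 0.18, 0.25, 0.10, 0.02],
             [4.79, 2.76, 2.25, 1.06, 0.48], [0.26, 0.16, 0.24, 0.08, 0.01]),
        20: ([19.2, 14.9, 11.9, 3.69, 2.47], [0.36, 0.18, 0.25, 0.10, 0.02],
             [4.95, 2.02, 1.68, 0.64, 0.50], [0.26, 0.16, 0.24, 0.08, 0.01]),
        25: ([15.5, 12.5, 8.03, 2.96, 1.63], [0.34, 0.49, 0.13, 0.03, 0.02],
             [2.99, 2.57, 1.49, 0.60, 0.21], [0.28, 0.33, 0.12, 0.03, 0.02]),
        50: ([8.11, 5.47, 3.77, 1.79, 0.93], [0.07, 0.17, 0.03, 0.03, 0.01],
             [1.39, 1.24, 0.47, 0.34, 0.16], [0.08, 0.10, 0.02, 0.02, 0.01]),
        75: ([6.03, 3.99, 2.73, 0.97, 0.68], [0.03, 0.04, 0.02, 0.02, 0.01],
             [0.86, 0.65, 0.27, 0.17, 0.15], [0.03, 0.03, 0.02, 0.01, 0.01]),
        100: ([4.26, 3.12, 2.06, 0.97, 0.46], [0.03, 0.07, 0.02, 0.02, 0.01],
              [0.58, 0.53, 0.31, 0.09, 0.08], [0.03, 0.07, 0.01, 0.01, 0.01]),
    },
    "LP": {
        100: ([33.1, 14.0, 7.90, 3.15, 1.15], [0.33, 0.42, 0.13, 0.06, 0.02],
              [10.9, 4.26, 1.84, 0.79, 0.27], [0.25, 0.31, 0.12, 0.06, 0.02]),
        150: ([21.4, 12.1, 8.77, 1.81, 0.77], [0.80, 0.16, 0.15, 0.04, 0.03],
              [8.60, 2.09, 2.52, 0.57, 0.18], [0.79, 0.14, 0.13, 0.03, 0.03]),
        300: ([11.3, 3.49, 1.38, 0.85, 0.30], [0.40, 0.14, 0.04, 0.02, 0.03],
              [3.49, 0.86, 0.38, 0.23, 0.06], [0.36, 0.14, 0.04, 0.01, 0.03]),
        500: ([9.87, 4.03, 1.75, 0.49, 0.20], [0.10, 0.06, 0.03, 0.01, 0.01],
              [2.25, 1.01, 0.41, 0.14, 0.05], [0.09, 0.06, 0.02, 0.01, 0.01]),
    },
}


def tti_rate_constants() -> pd.DataFrame:
    """Measured logistic constants k1, k2 (days) per label x temperature.

    Columns: tti_type, enzyme_units, temperature_C, k1, k1_se, k2, k2_se.
    """
    rows = []
    for tti_type, concs in _TTI.items():
        for c, (k1s, k1se, k2s, k2se) in concs.items():
            for i, t_c in enumerate(_TTI_TEMPS_C):
                rows.append({"tti_type": tti_type, "enzyme_units": float(c),
                             "temperature_C": t_c, "k1": k1s[i],
                             "k1_se": k1se[i], "k2": k2s[i], "k2_se": k2se[i]})
    return pd.DataFrame(rows)


def tti_global_models() -> dict[str, TTIGlobalResults]:
    """Published global concentration-temperature models per TTI chemistry."""
    return {
        "M": TTIGlobalResults(tti_type="M", ea=97_100.0, k1ref_c1=128.6,
                              k2ref_c1=25.7, alpha=0.861, beta=0.861,
                              rsquared=0.970),
        "LP": TTIGlobalResults(tti_type="LP", ea=148_000.0, k1ref_c1=1822.4,
                               k2ref_c1=298.1, alpha=1.10, beta=0.970,
                               rsquared=0.967),
    }


def dynamic_observed_rates() -> pd.DataFrame:
    """Growth rates fitted to counts observed in the Teff = 4.8 degC trial."""
    rows = [
        ("TVC", "MAP_PAD", 0.348, 0.015), ("TVC", "MAP", 0.551, 0.073),
        ("Pseudomonas", "MAP_PAD", 0.355, 0.041), ("Pseudomonas", "MAP", 0.367, 0.049),
        ("Enterobacteriaceae", "MAP_PAD", 0.493, 0.0282),
        ("Enterobacteriaceae", "MAP", 0.510, 0.025),
        ("H2S_producers", "MAP_PAD", 0.276, 0.043),
        ("H2S_producers", "MAP", 0.467, 0.047),
    ]
    return pd.DataFrame(rows, columns=["organism", "packaging", "k", "k_se"])


def dynamic_predicted_rates() -> pd.DataFrame:
    """Model-predicted rates for the same trial, with the published RE%."""
    rows = [
        ("TVC", "MAP_PAD", 0.398, 0.024, 14), ("TVC", "MAP", 0.524, 0.046, 5),
        ("Pseudomonas", "MAP_PAD", 0.244, 0.012, 31),
        ("Pseudomonas", "MAP", 0.321, 0.009, 12),
        ("Enterobacteriaceae", "MAP_PAD", 0.401, 0.015, 18),
        ("Enterobacteriaceae", "MAP", 0.486, 0.023, 5),
        ("H2S_producers", "MAP_PAD", 0.351, 0.025, 27),
        ("H2S_producers", "MAP", 0.447, 0.0017, 2),
    ]
    return pd.DataFrame(rows, columns=["organism", "packaging", "k_pred",
                                       "k_pred_se", "re_percent_published"])


def reference_shelf_spec(packaging: str, organism: str = "TVC",
                         log_n0: float = INITIAL_TVC_LOG10,
                         log_n1: float = 7.0) -> ShelfLifeSpec:
    """Shelf-life spec assembled from the published kinetic tables.

    Uses the published activation energy for the organism/packaging and
    estimates the reference rate and lag from the per-temperature Baranyi
    constants with that Ea held fixed:

        kref    = exp(mean_i[ln k_i + (Ea/R) x_i]),
        lag_ref = exp(mean_i[ln lag_i - (Ea/R) x_i]),

    with x_i = 1/T_i - 1/Tref (the intercepts of the two Arrhenius lines
    through the table values).
    """
    gp = growth_parameters()
    sub = gp[(gp.organism == organism) & (gp.packaging == packaging)]
    if sub.empty:
        raise KeyError(f"no reference data for {organism}/{packaging}")
    ea_tab = activation_energies()
    ea = float(ea_tab[(ea_tab.organism == organism)
                      & (ea_tab.packaging == packaging)]
               ["ea_kj_per_mol"].iloc[0]) * 1000.0
    temps_k = sub["temperature_C"].to_numpy() + 273.15
    x = 1.0 / temps_k - 1.0 / TREF_DEFAULT_K
    kref = float(np.exp(np.mean(np.log(sub["k"].to_numpy()) + ea / R_GAS * x)))
    lag_pts = [(t, None if np.isnan(l) else l)
               for t, l in zip(temps_k, sub["lag_d"])]
    lag_ref, _ = fit_lag_reference(lag_pts, ea, TREF_DEFAULT_K)
    rate = ArrheniusResults(kref=kref, ea=ea, direction="rate_like",
                            tref_k=TREF_DEFAULT_K)
    return ShelfLifeSpec(rate_model=rate, log_n0=log_n0, log_n1=log_n1,
                         lag_ref=lag_ref, label=f"{organism}/{packaging}")
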