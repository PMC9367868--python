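"""Matching a TTI label to a product's shelf-life behavior.

Two selection criteria are applied.  First, the activation energy of the
label's response must lie within +-20 kJ/mol of the activation energy of
the product's quality-deterioration rate; labels failing this are not
considered.  Second, over the chill-chain temperature range (0-10 degC by
default) the label's end-point response time should track the product's
shelf-life curve; candidates are ranked by the maximum absolute relative
deviation between the two curves, with ties broken in favor of labels that
are conservative at abuse temperatures (expiring at or before the shelf
life for every grid temperature above the abuse threshold, 6 degC by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .shelflife import ShelfLifeSpec, shelf_life_curve
from .tti import ENDPOINT_DEFAULT, TTIGlobalResults

EA_WINDOW_J = 20_000.0
ABUSE_THRESHOLD_K = 273.15 + 6.0
DEFAULT_GRID_K = 273.15 + np.arange(0.0, 10.0 + 1e-9, 0.5)

__all__ = [
    "EA_WINDOW_J",
    "ABUSE_THRESHOLD_K",
    "DEFAULT_GRID_K",
    "MatchReport",
    "ea_compatible",
    "match_score",
    "select_tti",
]


def ea_compatible(ea_product: float, ea_tti: float,
                  window_j: float = EA_WINDOW_J) -> bool:
    """True when the two activation energies (J/mol) differ by <= window."""
    if not (ea_product > 0 and ea_tti > 0):
        raise ParameterError("activation energies must be positive")
    return abs(ea_product - ea_tti) <= window_j


@dataclass
class MatchReport:
    """Comparison of one TTI candidate against a product shelf-life curve.

    ``table`` has one row per grid temperature with columns
    (temperature_K, shelf_life_d, tti_response_d, relative_deviation),
    where relative_deviation = (tti - shelf_life) / shelf_life.
    """

    label: str
    ea_product: float
    ea_tti: float
    ea_compatible: bool
    table: pd.DataFrame
    max_abs_relative_deviation: float
    conservative_at_abuse: bool

    def summary(self) -> str:
        return (f"{self.label}: Ea {self.ea_tti / 1000:.1f} vs product "
                f"{self.ea_product / 1000:.1f} kJ/mol "
                f"({'compatible' if self.ea_compatible else 'INCOMPATIBLE'}); "
                f"max |rel dev| = {self.max_abs_relative_deviation:.3f}; "
                f"conservative at abuse: {self.conservative_at_abuse}")


def match_score(shelf_curve, tti_curve, abuse_threshold_k=ABUSE_THRESHOLD_K,
                *, label="TTI", ea_product=np.nan, ea_tti=np.nan) -> MatchReport:
    """Score one TTI end-point curve against a shelf-life curve.

    Both curves are (n, 2) arrays of (T_K, days) on the same grid.
    """
    sc = np.asarray(shelf_curve, dtype=float)
    tc = np.asarray(tti_curve, dtype=float)
    if sc.shape != tc.shape or not np.allclose(sc[:, 0], tc[:, 0]):
        raise ParameterError("shelf and TTI curves must share one temperature grid")
    rel = (tc[:, 1] - sc[:, 1]) / sc[:, 1]
    abuse = sc[:, 0] > abuse_threshold_k
    conservative = bool(np.all(tc[abuse, 1] <= sc[abuse, 1])) if abuse.any() else True
    table = pd.DataFrame({
        "temperature_K": sc[:, 0],
        "shelf_life_d": sc[:, 1],
        "tti_response_d": tc[:, 1],
        "relative_deviation": rel,
    })
    compatible = (bool(ea_compatible(ea_product, ea_tti))
                  if np.isfinite(ea_product) and np.isfinite(ea_tti) else True)
    return MatchReport(
        label=label, ea_product=float(ea_product), ea_tti=float(ea_tti),
        ea_compatible=compatible, table=table,
        max_abs_relative_deviation=float(np.max(np.abs(rel))),
        conservative_at_abuse=conservative)


def select_tti(product_spec: ShelfLifeSpec, candidates,
               grid_k=None, abuse_threshold_k=ABUSE_THRESHOLD_K,
               endpoint=ENDPOINT_DEFAULT, ea_window_j=EA_WINDOW_J):
    """Rank TTI candidates for a product.

    Parameters
    ----------
    product_spec : ShelfLifeSpec
        The product's shelf-life model; its rate-model Ea is the
        compatibility reference.
    candidates : iterable of (TTIGlobalResults, C) pairs
        Each pair is one label chemistry at one enzyme load.
    grid_k : array_like, optional
        Temperature grid (K); defaults to 0-10 degC in 0.5 degC steps.

    Returns
    -------
    list of MatchReport
        Ea-compatible candidates ranked by ascending maximum absolute
        relative deviation, ties broken in favor of conservative labels.
        Empty when no candidate passes the Ea filter.
    """
    grid = DEFAULT_GRID_K if grid_k is None else np.asarray(grid_k, dtype=float)
    cands = list(candidates)
    if not cands:
        raise ParameterError("need at least one candidate")
    shelf = shelf_life_curve(product_spec, grid)
    reports = []
    for model, conc in cands:
        if not isinstance(model, TTIGlobalResults):
            raise ParameterError("candidates must be (TTIGlobalResults, C) pairs")
        if not ea_compatible(product_spec.ea, model.ea, ea_window_j):
            continue
        tti_days = model.response_time(conc, grid, endpoint=endpoint)
        tti_curve = np.column_stack([grid, tti_days])
        label = f"{model.tti_type or 'TTI'}-{conc:g}U"
        reports.append(match_score(
            shelf, tti_curve, abuse_threshold_k, label=label,
            ea_product=product_spec.ea, ea_tti=model.ea))
    # stable sort => input-order independence is restored by sorting on the
    # (score, non-conservative, label) key
    reports.sort(key=lambda r: (r.max_abs_relative_deviation,
                                not r.conservative_at_abuse, r.label))
    return reports
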