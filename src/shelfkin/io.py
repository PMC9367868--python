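"""Table readers/writers, run configuration and the end-to-end pipeline.

File conventions: temperatures are stored in degC in files and converted
to kelvin at this boundary; times are in days; activation energies are
reported in kJ/mol externally and carried in J/mol internally.  Delimited
tables use a header row and the decimal point (not comma).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrhenius import ArrheniusModel, RatePoint, celsius_to_kelvin, \
    fit_lag_reference
from .baranyi import BaranyiModel
from .dynamic import TemperatureProfile
from .exceptions import TableFormatError
from .matching import select_tti
from .shelflife import ShelfLifeSpec, shelf_life_curve
from .tti import ColorReading, TTISeries, TTIGlobalModel, TTILogisticModel

log = logging.getLogger("shelfkin")

COUNT_COLUMNS = ["organism", "packaging", "temperature_C", "time_d",
                 "log10_count", "replicate"]
COLOR_COLUMNS = ["tti_type", "enzyme_units", "temperature_C", "time_d",
                 "a", "b", "replicate"]
PROFILE_COLUMNS = ["time_d", "temperature_C"]

__all__ = [
    "PipelineConfig",
    "read_counts", "read_colors", "read_profile",
    "write_counts", "write_colors", "write_profile",
    "run_pipeline",
]


def _read_table(path, required, numeric):
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        bad = []
        def conv(v, i):
            try:
                return float(v)
            except (TypeError, ValueError):
                bad.append((i + 2, v))  # +2: header line + 1-based
                return np.nan
        df[col] = [conv(v, i) for i, v in enumerate(df[col])]
        if bad:
            line, val = bad[0]
            hint = (" (comma decimal? use a point)" if
                    isinstance(val, str) and "," in val else "")
            raise TableFormatError(
                f"{path}: column {col!r} not numeric at line {line}: "
                f"{val!r}{hint}; {len(bad)} malformed row(s)")
    return df


def read_counts(path) -> pd.DataFrame:
    """Read a microbial count table (CSV, COUNT_COLUMNS schema)."""
    return _read_table(path, COUNT_COLUMNS,
                       ["temperature_C", "time_d", "log10_count"])


def read_colors(path) -> pd.DataFrame:
    """Read a TTI color-reading table (CSV, COLOR_COLUMNS schema)."""
    return _read_table(path, COLOR_COLUMNS,
                       ["enzyme_units", "temperature_C", "time_d", "a", "b"])


def read_profile(path) -> TemperatureProfile:
    """Read a logger-style profile (CSV: time_d, temperature_C).

    Row i gives the temperature holding from time_d[i] to time_d[i+1];
    the last row closes the profile (its temperature is ignored unless it
    is the only pair, which is invalid).
    """
    df = _read_table(path, PROFILE_COLUMNS, ["time_d", "temperature_C"])
    t = df["time_d"].to_numpy()
    temps = df["temperature_C"].to_numpy()
    if t.size < 2:
        raise TableFormatError(f"{path}: a profile needs >= 2 rows")
    segs = [(t[i], t[i + 1], temps[i]) for i in range(t.size - 1)]
    return TemperatureProfile.from_celsius_segments(segs)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COUNT_COLUMNS)


def write_colors(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COLOR_COLUMNS)


def write_profile(profile: TemperatureProfile, path) -> None:
    rows = [(a, t - 273.15) for a, _, t in profile.segments]
    rows.append((profile.total_duration, rows[-1][1]))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def series_from_frame(df: pd.DataFrame) -> TTISeries:
    """Build a TTISeries from color rows of a single label (one C, one T)."""
    g = df.groupby("time_d", sort=True)[["a", "b"]].mean()
    readings = [ColorReading(time_d=float(t), a=float(r["a"]), b=float(r["b"]))
                for t, r in g.iterrows()]
    return TTISeries(
        readings=readings,
        tti_type=str(df["tti_type"].iloc[0]),
        enzyme_units=float(df["enzyme_units"].iloc[0]),
        temperature_c=float(df["temperature_C"].iloc[0]))


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Paths may be None to skip the corresponding stages (e.g. no color
    table: growth/shelf-life stages still run, TTI stages are skipped).
    """

    counts_path: str | None = None
    colors_path: str | None = None
    profile_path: str | None = None
    out_dir: str = "shelfkin_reports"
    tref_c: float = 4.0
    log_n1: float = 7.0
    log_n0: float | None = None    # default: first observed TVC count
    endpoint: float = 0.8
    ea_window_kj: float = 20.0
    abuse_threshold_c: float = 6.0
    seed: int = 0
    grid_c: tuple = tuple(np.arange(0.0, 10.5, 0.5))

    def __post_init__(self):
        for name in ("log_n1", "endpoint", "ea_window_kj"):
            if not getattr(self, name) > 0:
                raise TableFormatError(f"config {name} must be positive")
        if not -5.0 <= self.tref_c <= 25.0:
            raise TableFormatError("tref_c outside the supported range")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fit-growth -> fit-arrhenius -> shelf-life -> fit-tti -> match
    -> validate, writing JSON reports under ``config.out_dir``.

    Returns the report bundle as a dict.  Stages without inputs are
    marked "skipped".  Identical config + inputs give byte-identical
    reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tref_k = float(celsius_to_kelvin(config.tref_c))
    grid_k = celsius_to_kelvin(np.asarray(config.grid_c))
    bundle: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": _jsonify({k: v for k, v in vars(config).items()}),
            "input_hashes": {},
        },
        "stages": {},
    }

    growth_fits = {}
    arrhenius_fits = {}
    shelf_specs = {}

    if config.counts_path:
        bundle["provenance"]["input_hashes"]["counts"] = _sha256(config.counts_path)
        counts = read_counts(config.counts_path)
        stage = {}
        for (org, pack, t_c), sub in counts.groupby(
                ["organism", "packaging", "temperature_C"]):
            res = BaranyiModel.from_dataframe(sub).fit(with_lag="auto")
            growth_fits[(org, pack, t_c)] = res
            stage[f"{org}/{pack}/{t_c:g}C"] = {
                "y0": res.params.y0, "ymax": res.params.ymax,
                "mu": res.params.mu, "lag_d": res.params.lag,
                "r_squared": res.rsquared, "lag_dropped": res.lag_dropped}
        bundle["stages"]["fit_growth"] = stage

        stage = {}
        for (org, pack), keys in _group_conditions(growth_fits):
            pts = [RatePoint(float(celsius_to_kelvin(t_c)),
                             growth_fits[(org, pack, t_c)].params.mu)
                   for t_c in keys]
            fit = ArrheniusModel(pts, direction="rate_like",
                                 tref_k=tref_k).fit()
            lag_pts = [(float(celsius_to_kelvin(t_c)),
                        growth_fits[(org, pack, t_c)].params.lag)
                       for t_c in keys]
            lag_ref, absent = fit_lag_reference(lag_pts, fit.ea, tref_k)
            arrhenius_fits[(org, pack)] = (fit, lag_ref)
            stage[f"{org}/{pack}"] = fit.to_report() | {"lag_ref_d": lag_ref}
        bundle["stages"]["fit_arrhenius"] = stage

        stage = {}
        for (org, pack), (fit, lag_ref) in arrhenius_fits.items():
            if org != "TVC":
                continue
            sub = counts[(counts.organism == org) & (counts.packaging == pack)]
            log_n0 = (config.log_n0 if config.log_n0 is not None else
                      float(sub.sort_values("time_d")["log10_count"].iloc[0]))
            spec = ShelfLifeSpec(rate_model=fit, log_n0=log_n0,
                                 log_n1=config.log_n1, lag_ref=lag_ref,
                                 label=f"TVC/{pack}")
            shelf_specs[pack] = spec
            curve = shelf_life_curve(spec, grid_k)
            stage[pack] = {
                "log_n0": log_n0,
                "temperatures_C": list(np.round(np.asarray(config.grid_c), 3)),
                "shelf_life_d": list(curve[:, 1]),
            }
        bundle["stages"]["shelf_life"] = stage
    else:
        for s in ("fit_growth", "fit_arrhenius", "shelf_life"):
            bundle["stages"][s] = "skipped"

    tti_models = {}
    if config.colors_path:
        bundle["provenance"]["input_hashes"]["colors"] = _sha256(config.colors_path)
        colors = read_colors(config.colors_path)
        stage = {}
        label_fits = {}
        for (tti_type, c, t_c), sub in colors.groupby(
                ["tti_type", "enzyme_units", "temperature_C"]):
            series = series_from_frame(sub)
            res = TTILogisticModel.from_series(series).fit()
            label_fits.setdefault(tti_type, []).append((c, t_c, res.params))
            stage[f"{tti_type}-{c:g}U/{t_c:g}C"] = {
                "k1_d": res.k1, "k2_d": res.k2, "r_squared": res.rsquared}
        bundle["stages"]["fit_tti_labels"] = stage

        stage = {}
        for tti_type, fits in label_fits.items():
            try:
                res = TTIGlobalModel(fits, tti_type=tti_type,
                                     tref_k=tref_k).fit()
            except Exception as exc:  # narrow designs in partial runs
                stage[tti_type] = {"error": str(exc)}
                continue
            tti_models[tti_type] = res
            stage[tti_type] = res.to_report()
        bundle["stages"]["fit_tti_global"] = stage
    else:
        bundle["stages"]["fit_tti_labels"] = "skipped"
        bundle["stages"]["fit_tti_global"] = "skipped"

    if shelf_specs and tti_models:
        colors = read_colors(config.colors_path)
        stage = {}
        for pack, spec in shelf_specs.items():
            candidates = [
                (tti_models[tt], float(c))
                for tt in sorted(tti_models)
                for c in sorted(colors[colors.tti_type == tt]
                                ["enzyme_units"].unique())]
            ranking = select_tti(
                spec, candidates, grid_k=grid_k,
                abuse_threshold_k=float(celsius_to_kelvin(config.abuse_threshold_c)),
                endpoint=config.endpoint,
                ea_window_j=config.ea_window_kj * 1000.0)
            stage[pack] = [
                {"label": r.label,
                 "max_abs_relative_deviation": r.max_abs_relative_deviation,
                 "conservative_at_abuse": r.conservative_at_abuse}
                for r in ranking]
        bundle["stages"]["match"] = stage
    else:
        bundle["stages"]["match"] = "skipped"

    if config.profile_path and arrhenius_fits:
        bundle["provenance"]["input_hashes"]["profile"] = _sha256(config.profile_path)
        from .dynamic import effective_temperature, predict_growth_dynamic, \
            apparent_growth_rate
        profile = read_profile(config.profile_path)
        stage = {}
        for (org, pack), (fit, lag_ref) in arrhenius_fits.items():
            teff = effective_temperature(profile, fit.ea, tref_k)
            ref = growth_fits[min(k for k in growth_fits
                                  if k[0] == org and k[1] == pack)]
            params = ref.params
            from .baranyi import BaranyiParams
            ref_params = BaranyiParams(y0=params.y0, ymax=params.ymax,
                                       mu=fit.kref, lag=lag_ref or None)
            t, y = predict_growth_dynamic(ref_params, fit, profile)
            k_pred = apparent_growth_rate(t, y).mu
            stage[f"{org}/{pack}"] = {
                "teff_C": teff - 273.15, "k_predicted": k_pred}
        bundle["stages"]["validate"] = stage
    else:
        bundle["stages"]["validate"] = "skipped"

    bundle = _jsonify(bundle)
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    log.info("pipeline report written to %s (seed=%s, version=%s)",
             report_path, config.seed, __version__)
    return bundle


def _group_conditions(growth_fits):
    """Yield ((org, pack), sorted temperature keys) with >= 3 temperatures."""
    groups = {}
    for (org, pack, t_c) in growth_fits:
        groups.setdefault((org, pack), []).append(t_c)
    for key, temps in sorted(groups.items()):
        if len(temps) >= 3:
            yield key, sorted(temps)
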