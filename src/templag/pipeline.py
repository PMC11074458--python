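"""End-to-end analysis runner: descriptives, per-subgroup DLNM
case-crossover fits, effect tables and the sensitivity grid.

The input is a delimited daily table (one row per calendar day, ISO
dates) with outcome counts per transport-mode subgroup, daily mean
temperature, relative humidity, barometric pressure, wind speed and six
pollutant concentrations.  Missing values are empty fields; rows with a
missing exposure are dropped with a logged count.

Each subgroup model shares the same exposure cross-basis and confounder
design and differs only in the outcome column.  The "other" transport
category is summarized descriptively but never modelled (residual
heterogeneous category with too few events).  Every number in a report
is regenerable from the provenance block (config hash, seed, package
version) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossbasis import CrossBasisSpec, build_crossbasis
from .descriptives import spearman_matrix, summarize_continuous, summarize_counts
from .design import (
    POLLUTANT_COLUMNS,
    assign_strata,
    build_confounder_design,
    select_pollutants,
)
from .effects import (
    EffectTable,
    build_effect_table,
    cumulative_or,
    exposure_response_curve,
    extreme_thresholds,
    find_mmt,
)
from .errors import SchemaError, TemplagError
from .fit import fit_conditional_poisson
from .simulate import SERIES_COLUMNS
from .splines import make_spec

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "read_series",
    "validate_series",
    "run_analysis",
    "run_sensitivity",
]

log = logging.getLogger("templag")

MODELLED_SUBGROUPS = ("total", "walking", "bicycle", "motorcycle", "motorvehicle")
DESCRIBED_SUBGROUPS = MODELLED_SUBGROUPS[1:] + ("other",)
METEO_COLUMNS = ("temp_mean_c", "rh_pct", "bp_hpa", "ws_ms") + POLLUTANT_COLUMNS


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the main analysis and its sensitivity grid."""

    max_lag: int = 14
    exposure_df: int = 2
    lag_df: int = 2
    humidity_df: int = 3
    pollutant_df: int = 2
    pollutants: tuple[str, ...] | None = None  # None -> correlation screen
    strong_corr_threshold: float = 0.6
    include_pressure: bool = False
    include_wind: bool = False
    p_low: float = 1.0
    p_high: float = 99.0
    subgroups: tuple[str, ...] = MODELLED_SUBGROUPS
    curve_points: int = 100
    mmt_grid: int = 1000
    sensitivity_lags: tuple[int, ...] = (7, 14, 21)
    sensitivity_confounder_dfs: tuple[int, ...] = (2, 3, 4)
    sensitivity_percentiles: tuple[tuple[float, float], ...] = ((1.0, 99.0), (2.5, 97.5), (10.0, 90.0))
    sensitivity_all_subgroups: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise SchemaError("max_lag must be >= 0")
        for name in ("exposure_df", "lag_df", "humidity_df", "pollutant_df"):
            if getattr(self, name) < 1:
                raise SchemaError(f"{name} must be >= 1")
        if not 0.0 < self.p_low < self.p_high < 100.0:
            raise SchemaError("need 0 < p_low < p_high < 100")
        for attr in ("pollutants", "subgroups", "sensitivity_lags", "sensitivity_confounder_dfs"):
            value = getattr(self, attr)
            if value is not None:
                object.__setattr__(self, attr, tuple(value))
        object.__setattr__(
            self,
            "sensitivity_percentiles",
            tuple(tuple(float(p) for p in pair) for pair in self.sensitivity_percentiles),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise SchemaError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["pollutants"] = list(out["pollutants"]) if out["pollutants"] is not None else None
        for key in ("subgroups", "sensitivity_lags", "sensitivity_confounder_dfs"):
            out[key] = list(out[key])
        out["sensitivity_percentiles"] = [list(p) for p in out["sensitivity_percentiles"]]
        return out

    def digest(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class SubgroupResult:
    """One subgroup's fitted model and report tables."""

    subgroup: str
    mmt: float
    thresholds: tuple[float, float]
    effect_table: EffectTable
    curve: pd.DataFrame
    fit_summary: dict


@dataclass
class RunReport:
    """All artifacts of one analysis (or sensitivity) run."""

    descriptives: dict[str, pd.DataFrame]
    subgroups: dict[str, SubgroupResult]
    failures: dict[str, str]
    sensitivity: pd.DataFrame | None
    provenance: dict

    def write(self, outdir) -> None:
        """Write delimited report tables plus a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.descriptives.items():
            table.to_csv(outdir / f"descriptives_{name}.csv", lineterminator="\n")
        for name, res in self.subgroups.items():
            rounded = res.effect_table.rounded(3)
            rounded.cumulative.to_csv(
                outdir / f"effects_cumulative_{name}.csv", index=False, lineterminator="\n"
            )
            rounded.single_lag.to_csv(
                outdir / f"effects_single_lag_{name}.csv", index=False, lineterminator="\n"
            )
            res.curve.round(4).to_csv(
                outdir / f"curve_{name}.csv", index=False, lineterminator="\n"
            )
        if self.sensitivity is not None:
            self.sensitivity.round(4).to_csv(
                outdir / "sensitivity_grid.csv", index=False, lineterminator="\n"
            )
        manifest = dict(self.provenance)
        manifest["subgroup_summaries"] = {
            name: {
                "mmt": round(res.mmt, 3),
                "threshold_low": round(res.thresholds[0], 3),
                "threshold_high": round(res.thresholds[1], 3),
                **res.fit_summary,
            }
            for name, res in self.subgroups.items()
        }
        manifest["failures"] = dict(self.failures)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def validate_series(frame: pd.DataFrame) -> None:
    """Reject, with a named error, any table missing a required column."""
    missing = [c for c in SERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"daily series is missing required columns: {missing}")


def read_series(path) -> pd.DataFrame:
    """Read and validate the delimited daily-series format.

    Rows with a missing exposure (temperature) are dropped with a
    logged count.
    """
    frame = pd.read_csv(path)
    validate_series(frame)
    frame["date"] = pd.to_datetime(frame["date"], errors="raise")
    n_missing = int(frame["temp_mean_c"].isna().sum())
    if n_missing:
        log.warning("dropping %d rows with missing exposure", n_missing)
        frame = frame[frame["temp_mean_c"].notna()].reset_index(drop=True)
    return frame


def _coerce(data) -> pd.DataFrame:
    if isinstance(data, (str, Path)):
        return read_series(data)
    frame = data.copy()
    validate_series(frame)
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


@dataclass
class _Prepared:
    frame: pd.DataFrame
    strata: object
    cb_spec: CrossBasisSpec
    crossbasis: object
    confounders: object
    pollutants: list[str]
    thresholds: tuple[float, float]


def prepare_design(
    frame: pd.DataFrame,
    config: AnalysisConfig,
    *,
    max_lag: int | None = None,
    humidity_df: int | None = None,
    p_low: float | None = None,
    p_high: float | None = None,
) -> _Prepared:
    """Build strata, cross-basis, confounder design and thresholds once;
    shared by all subgroup fits (and by sensitivity cells)."""
    max_lag = config.max_lag if max_lag is None else max_lag
    humidity_df = config.humidity_df if humidity_df is None else humidity_df
    p_low = config.p_low if p_low is None else p_low
    p_high = config.p_high if p_high is None else p_high

    temps = np.asarray(frame["temp_mean_c"], dtype=float)
    strata = assign_strata(frame["date"])
    exp_spec = make_spec(temps, config.exposure_df, "quantile", intercept=False)
    lag_spec = make_spec(np.arange(max_lag + 1), config.lag_df, "log-lag", intercept=True)
    cb_spec = CrossBasisSpec(exposure=exp_spec, lag=lag_spec, max_lag=max_lag)
    cb = build_crossbasis(temps, cb_spec)

    if config.pollutants is None:
        pollutants, _ = select_pollutants(frame, config.strong_corr_threshold)
    else:
        pollutants = list(config.pollutants)
    extra = {}
    if config.include_pressure:
        extra["bp_hpa"] = config.pollutant_df
    if config.include_wind:
        extra["ws_ms"] = config.pollutant_df
    confounders = build_confounder_design(
        frame, pollutants, humidity_df, config.pollutant_df, extra_variables=extra or None
    )
    thresholds = extreme_thresholds(temps, p_low, p_high)
    return _Prepared(frame, strata, cb_spec, cb, confounders, pollutants, thresholds)


def _count_column(subgroup: str) -> str:
    return "deaths_total" if subgroup == "total" else f"deaths_{subgroup}"


def _fit_subgroup(prep: _Prepared, subgroup: str):
    counts = np.asarray(prep.frame[_count_column(subgroup)])
    return fit_conditional_poisson(prep.crossbasis, prep.confounders, counts, prep.strata)


def analyze_subgroup(prep: _Prepared, subgroup: str, config: AnalysisConfig) -> SubgroupResult:
    """Fit one subgroup and derive its MMT-referenced effect tables."""
    fit = _fit_subgroup(prep, subgroup)
    temps = np.asarray(prep.frame["temp_mean_c"], dtype=float)
    mmt = find_mmt(fit, prep.cb_spec, temps, config.mmt_grid)
    table = build_effect_table(fit, prep.cb_spec, list(prep.thresholds), mmt)
    grid = np.linspace(temps.min(), temps.max(), config.curve_points)
    curve = exposure_response_curve(fit, prep.cb_spec, grid, mmt)
    return SubgroupResult(
        subgroup=subgroup,
        mmt=mmt,
        thresholds=prep.thresholds,
        effect_table=table,
        curve=curve,
        fit_summary={
            "converged": bool(fit.converged),
            "n_effective": int(fit.n_effective),
            "n_strata": int(fit.n_strata),
            "deviance": round(fit.deviance, 3),
        },
    )


def _descriptive_tables(frame: pd.DataFrame, config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    counts = summarize_counts(frame, [_count_column(g) for g in DESCRIBED_SUBGROUPS])
    continuous = summarize_continuous(frame, [c for c in METEO_COLUMNS if c in frame.columns])
    corr, flags = spearman_matrix(frame[[c for c in METEO_COLUMNS if c in frame.columns]],
                                  config.strong_corr_threshold)
    return {
        "counts": counts,
        "meteorology": continuous.round(3),
        "spearman": corr.round(3),
        "spearman_strong": flags,
    }


def _provenance(config: AnalysisConfig, frame: pd.DataFrame, pollutants) -> dict:
    return {
        "package": "templag",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "random_seed": config.random_seed,
        "n_days": int(len(frame)),
        "pollutants_adjusted": list(pollutants),
    }


def run_analysis(data, config: AnalysisConfig | None = None) -> RunReport:
    """Execute the full main analysis on a daily series (path or frame)."""
    config = config or AnalysisConfig()
    frame = _coerce(data)
    prep = prepare_design(frame, config)
    descriptives = _descriptive_tables(frame, config)

    subgroups: dict[str, SubgroupResult] = {}
    failures: dict[str, str] = {}
    for subgroup in config.subgroups:
        if subgroup == "other":
            log.info("subgroup 'other' is summarized but not modelled; skipping")
            continue
        try:
            subgroups[subgroup] = analyze_subgroup(prep, subgroup, config)
        except TemplagError as exc:
            log.warning("subgroup %s failed: %s", subgroup, exc)
            failures[subgroup] = str(exc)

    return RunReport(
        descriptives=descriptives,
        subgroups=subgroups,
        failures=failures,
        sensitivity=None,
        provenance=_provenance(config, frame, prep.pollutants),
    )


def run_sensitivity(data, config: AnalysisConfig | None = None) -> RunReport:
    """Execute the sensitivity grid {max lag} x {humidity df} x {percentiles}.

    The humidity (meteorological-confounder) spline df is varied with
    the pollutant df held at its main value, so the cell matching the
    main configuration reproduces the main estimates exactly.  Per cell
    and subgroup the lag-cumulated ORs at the extreme thresholds are
    tabulated at the full horizon and at the common horizon 7.
    """
    config = config or AnalysisConfig()
    frame = _coerce(data)
    subgroups = config.subgroups if config.sensitivity_all_subgroups else ("total",)

    rows = []
    failures: dict[str, str] = {}
    pollutants_used: list[str] = []
    for max_lag in config.sensitivity_lags:
        for hum_df in config.sensitivity_confounder_dfs:
            try:
                prep = prepare_design(frame, config, max_lag=max_lag, humidity_df=hum_df)
            except TemplagError as exc:
                failures[f"lag{max_lag}_df{hum_df}"] = str(exc)
                continue
            pollutants_used = prep.pollutants
            fits = {}
            for subgroup in subgroups:
                if subgroup == "other":
                    continue
                try:
                    fits[subgroup] = _fit_subgroup(prep, subgroup)
                except TemplagError as exc:
                    failures[f"lag{max_lag}_df{hum_df}_{subgroup}"] = str(exc)
            temps = np.asarray(frame["temp_mean_c"], dtype=float)
            for p_low, p_high in config.sensitivity_percentiles:
                t_low, t_high = extreme_thresholds(temps, p_low, p_high)
                for subgroup, fit in fits.items():
                    mmt = find_mmt(fit, prep.cb_spec, temps, config.mmt_grid)
                    for side, x in (("low", t_low), ("high", t_high)):
                        full = cumulative_or(fit, prep.cb_spec, x, mmt, max_lag)
                        h7 = cumulative_or(fit, prep.cb_spec, x, mmt, min(7, max_lag))
                        rows.append(
                            {
                                "max_lag": max_lag,
                                "humidity_df": hum_df,
                                "p_low": p_low,
                                "p_high": p_high,
                                "subgroup": subgroup,
                                "side": side,
                                "temperature": x,
                                "mmt": mmt,
                                "or_full": full.or_,
                                "ci_low_full": full.ci_low,
                                "ci_high_full": full.ci_high,
                                "or_h7": h7.or_,
                                "ci_low_h7": h7.ci_low,
                                "ci_high_h7": h7.ci_high,
                            }
                        )
    grid = pd.DataFrame(rows)
    return RunReport(
        descriptives={},
        subgroups={},
        failures=failures,
        sensitivity=grid,
        provenance=_provenance(config, frame, pollutants_used),
    )
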