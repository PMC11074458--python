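"""Time-stratified case-crossover strata and confounder design columns.

The time-stratified referent scheme compares each day with all other
days sharing its calendar year, calendar month and day of the week, so
every stratum holds 4 or 5 days ("up to 4 control days per case") and
seasonality, long-term trend and the day-of-week effect are removed by
design.  Weekdays follow the ISO convention (Monday = 1); any consistent
convention yields the same partition.

Confounders enter the model as natural cubic spline expansions: by
default relative humidity with 3 df and each selected pollutant with
2 df.  Pollutants are screened by their Spearman correlation with daily
mean temperature: those with |r| >= 0.6 (the conventional strong-
correlation cut) are excluded to avoid collinearity with the exposure;
the set can be overridden explicitly.  Barometric pressure and wind
speed are excluded from the default model but can be added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantVariableError, SchemaError, SpecError
from .splines import SplineSpec, evaluate_basis, make_spec

__all__ = [
    "StratumIndex",
    "ConfounderDesign",
    "assign_strata",
    "build_confounder_design",
    "select_pollutants",
    "POLLUTANT_COLUMNS",
]

POLLUTANT_COLUMNS = ("pm25", "pm10", "so2", "no2", "co", "o3_8h")


@dataclass(frozen=True)
class StratumIndex:
    """Per-day stratum labels of the form 'YYYY-MM-wdD' (ISO weekday D)."""

    labels: np.ndarray
    codes: np.ndarray
    levels: tuple[str, ...]

    @property
    def n_strata(self) -> int:
        return len(self.levels)

    def sizes(self) -> pd.Series:
        """Number of days in each stratum, indexed by label."""
        counts = np.bincount(self.codes, minlength=self.n_strata)
        return pd.Series(counts, index=list(self.levels), name="size")

    def days(self, label: str) -> np.ndarray:
        """Positions (into the original date vector) of a stratum's days."""
        code = self.levels.index(label)
        return np.flatnonzero(self.codes == code)


def assign_strata(dates) -> StratumIndex:
    """Assign each date to its (year, month, ISO weekday) stratum.

    Deterministic and independent of input ordering; dates need not be
    contiguous.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(dates, errors="raise"))
    if idx.isna().any():
        raise SchemaError("invalid dates in stratum assignment")
    iso_weekday = idx.dayofweek + 1
    labels = np.array(
        [f"{y:04d}-{m:02d}-wd{w}" for y, m, w in zip(idx.year, idx.month, iso_weekday)]
    )
    codes, levels = pd.factorize(labels, sort=True)
    return StratumIndex(labels=labels, codes=np.asarray(codes), levels=tuple(levels))


@dataclass(frozen=True)
class ConfounderDesign:
    """Concatenated spline expansions of the adjustment variables."""

    values: np.ndarray
    labels: tuple[str, ...]
    specs: dict[str, SplineSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.labels):
            raise SpecError("confounder design labels inconsistent with columns")
        if not np.all(np.isfinite(self.values)):
            raise SpecError("confounder design contains non-finite entries")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _spline_block(name: str, values: np.ndarray, df: int) -> tuple[np.ndarray, list[str], SplineSpec]:
    if np.unique(values).size < df + 1:
        raise ConstantVariableError(
            f"variable {name!r} has too few distinct values for a {df}-df spline"
        )
    spec = make_spec(values, df, "quantile", intercept=False)
    basis = evaluate_basis(spec, values).values
    return basis, [f"{name}_ns{i + 1}" for i in range(df)], spec


def build_confounder_design(
    series: pd.DataFrame,
    pollutants=(),
    humidity_df: int = 3,
    pollutant_df: int = 2,
    *,
    extra_variables: dict[str, int] | None = None,
) -> ConfounderDesign:
    """Assemble the confounder design: humidity spline + pollutant splines.

    ``extra_variables`` maps additional column names (e.g. ``bp_hpa``,
    ``ws_ms``) to spline df for non-default adjustment sets.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    specs: dict[str, SplineSpec] = {}

    plan: list[tuple[str, int]] = [("rh_pct", humidity_df)]
    for name in pollutants:
        if name not in POLLUTANT_COLUMNS:
            raise SchemaError(f"unknown pollutant {name!r}; expected one of {POLLUTANT_COLUMNS}")
        plan.append((name, pollutant_df))
    for name, df in (extra_variables or {}).items():
        plan.append((name, df))

    for name, df in plan:
        if name not in series.columns:
            raise SchemaError(f"confounder column {name!r} missing from series")
        values = np.asarray(series[name], dtype=float)
        if not np.all(np.isfinite(values)):
            raise SchemaError(f"confounder column {name!r} contains missing values")
        block, block_labels, spec = _spline_block(name, values, df)
        blocks.append(block)
        labels.extend(block_labels)
        specs[name] = spec

    return ConfounderDesign(values=np.column_stack(blocks), labels=tuple(labels), specs=specs)


def select_pollutants(
    series: pd.DataFrame,
    threshold: float = 0.6,
    candidates=POLLUTANT_COLUMNS,
    temperature_column: str = "temp_mean_c",
) -> tuple[list[str], dict[str, float]]:
    """Screen pollutants by Spearman correlation with daily mean temperature.

    Returns the pollutants whose |r| with temperature falls below
    ``threshold`` (kept for adjustment) together with all computed
    correlations.
    """
    corrs: dict[str, float] = {}
    keep: list[str] = []
    temp = series[temperature_column]
    for name in candidates:
        if name not in series.columns:
            continue
        r = float(temp.corr(series[name], method="spearman"))
        corrs[name] = r
        if abs(r) < threshold:
            keep.append(name)
    return keep, corrs
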