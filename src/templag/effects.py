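"""Reportable effect estimates from a fitted exposure-lag-response surface.

All effects are linear contrasts of the cross-basis coefficients.  For
exposure x against a reference ref at lag l the contrast vector is

    v(x, ref, l) = [Bx(x) - Bx(ref)] (kron) Bl(l)

so the log-OR is v.beta with delta-method variance v' Sigma v; the
cumulative effect over lags 0..h sums the per-lag contrast vectors, so
the cumulative log-OR equals the sum of the single-lag log-ORs exactly.
ORs and 95% CIs follow by exponentiation with z = 1.959964.

The minimum-mortality temperature (MMT) is the temperature minimizing
the overall cumulative (lag 0..L) exposure-response curve on a dense
grid over the observed range; it is recomputed per fitted model and the
report tables are then re-centred on it, since the reference is only
known after fitting.  Extreme thresholds are type-7 percentiles of the
observed daily means (1st/99th by default).

Evaluation outside the observed exposure range is refused by default
(natural-spline extrapolation is linear and easily misread); pass
``extrapolate=True`` to override.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .crossbasis import CrossBasisSpec
from .errors import ExtrapolationError, SpecError
from .fit import FitResult
from .splines import evaluate_basis

__all__ = [
    "EffectEstimate",
    "EffectTable",
    "single_lag_or",
    "cumulative_or",
    "exposure_response_curve",
    "find_mmt",
    "extreme_thresholds",
    "build_effect_table",
    "Z_95",
]

Z_95 = 1.959964


class EffectEstimate(NamedTuple):
    """An odds ratio with its 95% CI and log-scale components."""

    or_: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float


def _exposure_delta(spec: CrossBasisSpec, x: float, ref: float, extrapolate: bool) -> np.ndarray:
    b0, b1 = spec.exposure.boundary_knots
    for value, name in ((x, "x"), (ref, "ref")):
        if not extrapolate and not (b0 <= value <= b1):
            raise ExtrapolationError(
                f"{name}={value} lies outside the exposure range [{b0}, {b1}]; "
                "pass extrapolate=True to evaluate anyway"
            )
    bx = evaluate_basis(spec.exposure, [x, ref]).values
    return bx[0] - bx[1]


def _contrast_estimate(fit: FitResult, v: np.ndarray) -> EffectEstimate:
    beta = fit.beta[: v.size]
    cov = fit.cov[: v.size, : v.size]
    log_or = float(v @ beta)
    var = float(v @ cov @ v)
    se = float(np.sqrt(max(var, 0.0)))
    return EffectEstimate(
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        log_or=log_or,
        se=se,
    )


def single_lag_or(
    fit: FitResult,
    spec: CrossBasisSpec,
    x: float,
    ref: float,
    lag: int,
    *,
    extrapolate: bool = False,
) -> EffectEstimate:
    """OR with 95% CI at exposure ``x`` vs ``ref`` at a single lag day."""
    if not 0 <= lag <= spec.max_lag:
        raise SpecError(f"lag {lag} outside 0..{spec.max_lag}")
    dbx = _exposure_delta(spec, x, ref, extrapolate)
    bl = spec.lag_basis_values()[lag]
    return _contrast_estimate(fit, np.kron(dbx, bl))


def cumulative_or(
    fit: FitResult,
    spec: CrossBasisSpec,
    x: float,
    ref: float,
    horizon: int,
    *,
    extrapolate: bool = False,
) -> EffectEstimate:
    """Cumulative OR over lags 0..horizon at exposure ``x`` vs ``ref``."""
    if not 0 <= horizon <= spec.max_lag:
        raise SpecError(f"horizon {horizon} outside 0..{spec.max_lag}")
    dbx = _exposure_delta(spec, x, ref, extrapolate)
    bl_sum = spec.lag_basis_values()[: horizon + 1].sum(axis=0)
    return _contrast_estimate(fit, np.kron(dbx, bl_sum))


def exposure_response_curve(
    fit: FitResult,
    spec: CrossBasisSpec,
    grid,
    ref: float,
    *,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Overall cumulative (lag 0..L) curve on a temperature grid vs ``ref``."""
    grid = np.asarray(grid, dtype=float)
    bl_sum = spec.lag_basis_values().sum(axis=0)
    rows = []
    for x in grid:
        est = _contrast_estimate(
            fit, np.kron(_exposure_delta(spec, float(x), ref, extrapolate), bl_sum)
        )
        rows.append((float(x), est.log_or, est.se, est.or_, est.ci_low, est.ci_high))
    return pd.DataFrame(rows, columns=["temperature", "log_or", "se", "or", "ci_low", "ci_high"])


def find_mmt(fit: FitResult, spec: CrossBasisSpec, temperatures, n_grid: int = 1000) -> float:
    """Minimum-mortality temperature on an ``n_grid``-point grid.

    The overall cumulative curve is evaluated against a provisional
    reference (the curve's shape does not depend on it); ties break
    toward the lower temperature.
    """
    temps = np.asarray(temperatures, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise SpecError("no finite temperatures")
    grid = np.linspace(temps.min(), temps.max(), n_grid)
    bl_sum = spec.lag_basis_values().sum(axis=0)
    bx = evaluate_basis(spec.exposure, grid).values
    beta_cb = fit.beta[: spec.n_columns]
    # log-OR vs the grid's first point; any provisional reference shifts
    # the curve by a constant and leaves the argmin unchanged
    curve = (bx - bx[0]) @ _fold_lag(beta_cb, spec, bl_sum)
    if not np.all(np.isfinite(curve)):
        raise SpecError("non-finite exposure-response curve values")
    return float(grid[int(np.argmin(curve))])


def _fold_lag(beta_cb: np.ndarray, spec: CrossBasisSpec, bl_sum: np.ndarray) -> np.ndarray:
    """Collapse cross-basis coefficients over the lag dimension:
    returns g with g_j = sum_k beta_{jk} * sum_l Bl_k(l)."""
    return beta_cb.reshape(spec.exposure.df, spec.lag.df) @ bl_sum


def extreme_thresholds(temperatures, p_low: float = 1.0, p_high: float = 99.0) -> tuple[float, float]:
    """Low/high extreme-temperature thresholds as type-7 percentiles."""
    if not 0.0 < p_low < p_high < 100.0:
        raise SpecError("need 0 < p_low < p_high < 100")
    temps = np.asarray(temperatures, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise SpecError("empty temperature series")
    lo, hi = np.percentile(temps, [p_low, p_high])  # linear interpolation (type 7)
    return float(lo), float(hi)


@dataclass(frozen=True)
class EffectTable:
    """Single-lag and cumulative OR tables on a temperature grid vs the MMT."""

    reference: float
    single_lag: pd.DataFrame
    cumulative: pd.DataFrame

    def rounded(self, decimals: int = 3) -> "EffectTable":
        num = lambda df: df.round(decimals)
        return EffectTable(self.reference, num(self.single_lag), num(self.cumulative))


def build_effect_table(
    fit: FitResult,
    spec: CrossBasisSpec,
    temperatures,
    ref: float,
    *,
    extrapolate: bool = False,
) -> EffectTable:
    """Tabulate single-lag and cumulative ORs for each temperature vs ``ref``.

    Cumulative rows are labelled Lag0h (lags 0..h), the customary layout
    for reporting lag-cumulated case-crossover effects.
    """
    temps = np.atleast_1d(np.asarray(temperatures, dtype=float))
    single_rows, cum_rows = [], []
    for x in temps:
        for lag in range(spec.max_lag + 1):
            est = single_lag_or(fit, spec, float(x), ref, lag, extrapolate=extrapolate)
            single_rows.append((float(x), lag, est.log_or, est.se, est.or_, est.ci_low, est.ci_high))
        for h in range(spec.max_lag + 1):
            est = cumulative_or(fit, spec, float(x), ref, h, extrapolate=extrapolate)
            cum_rows.append(
                (float(x), h, f"Lag0{h}", est.log_or, est.se, est.or_, est.ci_low, est.ci_high)
            )
    single = pd.DataFrame(
        single_rows, columns=["temperature", "lag", "log_or", "se", "or", "ci_low", "ci_high"]
    )
    cum = pd.DataFrame(
        cum_rows,
        columns=["temperature", "horizon", "label", "log_or", "se", "or", "ci_low", "ci_high"],
    )
    return EffectTable(reference=float(ref), single_lag=single, cumulative=cum)
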