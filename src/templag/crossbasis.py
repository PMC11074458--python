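"""Bivariate exposure-lag cross-basis for distributed-lag nonlinear models.

The cross-basis realizes the log-risk surface f(x, l) as a tensor
product of an exposure spline basis Bx (df_x columns) and a lag spline
basis Bl (df_l columns).  Row t, column (j, k) of the design is

    sum_{l=0..L}  Bx_j(x_{t-l}) * Bl_k(l)

i.e. the lag-summed product of the exposure basis evaluated along the
exposure history and the lag basis evaluated at each lag.  Columns are
ordered exposure-major: column index = j * df_l + k, fixed so that
coefficient vectors are portable across runs.

The first L days of the series lack a complete exposure history; their
rows are set to NaN and flagged invalid rather than silently zeroed,
and are dropped from the likelihood at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .splines import SplineSpec, evaluate_basis, make_spec

__all__ = ["CrossBasisSpec", "CrossBasisMatrix", "build_crossbasis", "default_crossbasis_spec"]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure spline x lag spline cross-basis definition."""

    exposure: SplineSpec
    lag: SplineSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise SpecError("max_lag must be >= 0")
        lo, hi = self.lag.boundary_knots
        if (lo, hi) != (0.0, float(self.max_lag)):
            raise SpecError(
                f"lag basis boundary knots {self.lag.boundary_knots} must equal (0, {self.max_lag})"
            )

    @property
    def n_columns(self) -> int:
        return self.exposure.df * self.lag.df

    @property
    def column_labels(self) -> list[str]:
        return [
            f"cb_x{j + 1}_l{k + 1}"
            for j in range(self.exposure.df)
            for k in range(self.lag.df)
        ]

    def lag_basis_values(self) -> np.ndarray:
        """Lag basis evaluated at integer lags 0..L, shape (L+1, df_l)."""
        return evaluate_basis(self.lag, np.arange(self.max_lag + 1, dtype=float)).values


@dataclass(frozen=True)
class CrossBasisMatrix:
    """Realized cross-basis design columns for a daily exposure series."""

    values: np.ndarray
    valid: np.ndarray
    spec: CrossBasisSpec

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.spec.n_columns:
            raise SpecError("cross-basis column count inconsistent with spec")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise SpecError("valid cross-basis rows contain non-finite entries")


def default_crossbasis_spec(
    exposure_values,
    max_lag: int = 14,
    exposure_df: int = 2,
    lag_df: int = 2,
) -> CrossBasisSpec:
    """Standard cross-basis: quantile-knot exposure spline (no intercept),
    log-lag-knot lag spline (with intercept), over lags 0..max_lag."""
    exp_spec = make_spec(exposure_values, exposure_df, "quantile", intercept=False)
    lag_spec = make_spec(np.arange(max_lag + 1), lag_df, "log-lag", intercept=True)
    return CrossBasisSpec(exposure=exp_spec, lag=lag_spec, max_lag=max_lag)


def build_crossbasis(exposure, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Build the cross-basis design matrix for a daily exposure series.

    Raises on non-finite exposures or a series shorter than L + 1 days.
    """
    x = np.asarray(exposure, dtype=float).ravel()
    L = spec.max_lag
    if x.size < L + 1:
        raise SpecError(f"exposure series has {x.size} days; need at least max_lag+1 = {L + 1}")
    if not np.all(np.isfinite(x)):
        raise SpecError("exposure series contains non-finite values")

    bx = evaluate_basis(spec.exposure, x).values          # (n, df_x)
    bl = spec.lag_basis_values()                          # (L+1, df_l)
    n, df_x = bx.shape
    df_l = bl.shape[1]

    vals = np.zeros((n, df_x * df_l))
    for lag in range(L + 1):
        # rows t >= lag receive Bx(x_{t-lag}) (outer) Bl(lag)
        contrib = bx[: n - lag, :, None] * bl[lag][None, None, :]
        vals[lag:] += contrib.reshape(n - lag, df_x * df_l)
    valid = np.ones(n, dtype=bool)
    valid[:L] = False
    vals[:L] = np.nan
    return CrossBasisMatrix(values=vals, valid=valid, spec=spec)
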