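"""Effect contrasts: reference identities, cumulation, CIs, MMT, thresholds."""

import numpy as np
import pytest

from templag.crossbasis import CrossBasisSpec, default_crossbasis_spec
from templag.effects import (
    Z_95,
    build_effect_table,
    cumulative_or,
    extreme_thresholds,
    find_mmt,
    single_lag_or,
)
from templag.errors import ExtrapolationError, SpecError
from templag.fit import FitResult
from templag.splines import make_spec


def synthetic_fit(spec: CrossBasisSpec, beta_cb, seed=0) -> FitResult:
    """A FitResult with prescribed cross-basis coefficients and a random
    positive-definite covariance (the contrast identities are algebraic
    and hold for any coefficients)."""
    rng = np.random.default_rng(seed)
    p = spec.n_columns
    A = rng.normal(size=(p, p + 2)) * 0.05
    cov = A @ A.T + np.eye(p) * 1e-4
    return FitResult(
        beta=np.asarray(beta_cb, dtype=float),
        cov=cov,
        loglik=0.0,
        deviance=0.0,
        n_effective=100,
        n_strata=20,
        converged=True,
        n_iter=1,
        column_labels=tuple(spec.column_labels),
        n_crossbasis_columns=p,
    )


@pytest.fixture(scope="module")
def small_spec(ten_year_series):
    frame, _ = ten_year_series
    return default_crossbasis_spec(frame["temp_mean_c"], max_lag=14)


def test_reference_contrast_is_exactly_null(small_spec):
    fit = synthetic_fit(small_spec, np.arange(small_spec.n_columns) * 0.1)
    for lag in range(small_spec.max_lag + 1):
        est = single_lag_or(fit, small_spec, 10.0, 10.0, lag)
        assert est == (1.0, 1.0, 1.0, 0.0, 0.0)


def test_cumulative_equals_sum_of_single_lags(small_spec):
    fit = synthetic_fit(small_spec, [0.2, -0.1, 0.05, 0.15])
    for h in (0, 3, 14):
        cum = cumulative_or(fit, small_spec, 28.0, 12.0, h)
        singles = sum(
            single_lag_or(fit, small_spec, 28.0, 12.0, lag).log_or for lag in range(h + 1)
        )
        assert cum.log_or == pytest.approx(singles, abs=1e-12)
    h0 = cumulative_or(fit, small_spec, 28.0, 12.0, 0)
    l0 = single_lag_or(fit, small_spec, 28.0, 12.0, 0)
    assert h0 == l0


def test_linear_exposure_contrast_homogeneity(ten_year_series):
    """With a single linear exposure column, doubling (x - ref) exactly
    doubles the log-OR at every lag."""
    frame, _ = ten_year_series
    spec = default_crossbasis_spec(frame["temp_mean_c"], max_lag=5, exposure_df=1, lag_df=2)
    fit = synthetic_fit(spec, [0.3, -0.2])
    ref = 10.0
    for lag in range(6):
        one = single_lag_or(fit, spec, ref + 4.0, ref, lag).log_or
        two = single_lag_or(fit, spec, ref + 8.0, ref, lag).log_or
        assert two == pytest.approx(2.0 * one, rel=1e-10)


def test_delta_method_matches_parametric_bootstrap(total_fit):
    """10,000 draws of beta from its estimated Gaussian give a percentile
    CI whose log-width agrees with the delta-method interval within 3%."""
    prep, fit, _ = total_fit
    spec = prep.cb_spec
    rng = np.random.default_rng(314)
    draws = rng.multivariate_normal(fit.beta, fit.cov, size=10_000)
    temps = np.asarray(prep.frame["temp_mean_c"], dtype=float)
    _, x_high = extreme_thresholds(temps)
    for maker, arg in ((single_lag_or, 14), (cumulative_or, 14)):
        est = maker(fit, spec, x_high, 15.0, arg)
        # same contrast applied to each draw
        from templag.effects import _exposure_delta

        dbx = _exposure_delta(spec, x_high, 15.0, False)
        bl = spec.lag_basis_values()
        v = np.kron(dbx, bl[14] if maker is single_lag_or else bl[:15].sum(axis=0))
        sample = draws[:, : v.size] @ v
        lo, hi = np.quantile(sample, [0.025, 0.975])
        delta_width = 2 * Z_95 * est.se
        assert abs((hi - lo) - delta_width) / delta_width < 0.03
        assert abs(np.mean(sample) - est.log_or) < 4 * est.se / np.sqrt(10_000) + 1e-3


def test_ci_orders_and_positivity(total_fit):
    prep, fit, _ = total_fit
    temps = np.asarray(prep.frame["temp_mean_c"], dtype=float)
    x_low, x_high = extreme_thresholds(temps)
    table = build_effect_table(fit, prep.cb_spec, [x_low, x_high], 15.0)
    for frame in (table.single_lag, table.cumulative):
        assert (frame["ci_low"] > 0).all()
        assert (frame["ci_low"] <= frame["or"]).all()
        assert (frame["or"] <= frame["ci_high"]).all()
        assert np.allclose(frame["or"], np.exp(frame["log_or"]))


def test_mmt_boundary_for_increasing_curve(ten_year_series):
    """A strictly increasing overall curve puts the MMT at the observed
    minimum temperature (the boundary-minimum situation)."""
    frame, _ = ten_year_series
    temps = np.asarray(frame["temp_mean_c"], dtype=float)
    spec = default_crossbasis_spec(temps, max_lag=5, exposure_df=1, lag_df=2)
    fit = synthetic_fit(spec, [0.05, 0.01])  # positive slope at every lag
    assert find_mmt(fit, spec, temps) == pytest.approx(temps.min())


def test_mmt_ties_break_to_lowest_grid_point(ten_year_series):
    frame, _ = ten_year_series
    temps = np.asarray(frame["temp_mean_c"], dtype=float)
    spec = default_crossbasis_spec(temps, max_lag=5)
    fit = synthetic_fit(spec, np.zeros(spec.n_columns))  # constant (null) curve
    assert find_mmt(fit, spec, temps) == pytest.approx(temps.min())


def test_mmt_recovers_u_shape_minimum():
    """A high-event-rate ten-year run with the U-shaped truth (minimum at
    15 degC) recovers the MMT within 0.5 degC — the residual is spline-
    approximation error, since at 500 events/day the sampling noise in
    the curve minimum is small (documented tolerance)."""
    from templag.experiments import default_truth
    from templag.pipeline import AnalysisConfig, _fit_subgroup, prepare_design
    from templag.simulate import SimConfig, generate_series

    cfg = SimConfig(
        random_seed=1,
        truth_surface=default_truth("u-shaped"),
        baseline_daily_mean_deaths=500.0,
    )
    frame, truth = generate_series(cfg)
    prep = prepare_design(frame, AnalysisConfig())
    fit = _fit_subgroup(prep, "total")
    mmt = find_mmt(fit, prep.cb_spec, frame["temp_mean_c"])
    assert abs(mmt - truth.reference) < 0.5


def test_extreme_thresholds_type7():
    assert extreme_thresholds(np.arange(101.0)) == (1.0, 99.0)
    lo, hi = extreme_thresholds(np.array([1.0, 2.0, 3.0, 4.0, 100.0]), 50.0, 99.0)
    assert lo == 3.0  # hand-computed type-7 median of 5 points
    lo25, _ = extreme_thresholds(np.array([1.0, 2.0, 3.0, 4.0, 100.0]), 25.0, 99.0)
    assert lo25 == 2.0
    with pytest.raises(SpecError):
        extreme_thresholds([1.0, 2.0], 99.0, 1.0)
    with pytest.raises(SpecError):
        extreme_thresholds([])


def test_extrapolation_refused_by_default(total_fit):
    prep, fit, _ = total_fit
    b0, b1 = prep.cb_spec.exposure.boundary_knots
    with pytest.raises(ExtrapolationError):
        cumulative_or(fit, prep.cb_spec, b1 + 5.0, 15.0, 14)
    est = cumulative_or(fit, prep.cb_spec, b1 + 5.0, 15.0, 14, extrapolate=True)
    assert np.isfinite(est.log_or)
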