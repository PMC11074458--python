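"""Natural cubic spline basis: knot rules, span, boundary behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from templag.errors import SpecError
from templag.splines import SplineSpec, evaluate_basis, gcv_score, make_spec


def _truncated_power_natural_basis(x, knots):
    """Independent oracle: natural cubic spline basis via the classical
    truncated-power construction (1, x, d_k - d_{K-1} for interior k),
    which spans the same function space as any natural basis on the
    same knots."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def _span_residual(A, B):
    """Largest residual when regressing each column of B on A."""
    coef, *_ = np.linalg.lstsq(A, B, rcond=None)
    return np.abs(B - A @ coef).max()


def test_quantile_knot_placement(rng):
    x = rng.uniform(0, 30, 500)
    spec2 = make_spec(x, 2, "quantile")
    assert spec2.interior_knots == (pytest.approx(np.quantile(x, 0.5)),)
    assert spec2.boundary_knots == (pytest.approx(x.min()), pytest.approx(x.max()))

    # humidity-style 3-df spline: two interior knots at the tertiles
    spec3 = make_spec(x, 3, "quantile")
    expected = np.quantile(x, [1 / 3, 2 / 3])
    assert np.allclose(spec3.interior_knots, expected)


def test_explicit_knots_round_trip():
    spec = make_spec(
        None, 3, "explicit", boundary_knots=(0.0, 30.0), interior_knots=(10.0, 20.0)
    )
    assert spec.boundary_knots == (0.0, 30.0)
    assert spec.interior_knots == (10.0, 20.0)
    assert spec.df == 3


def test_df_consistency_enforced():
    with pytest.raises(SpecError):
        SplineSpec(df=4, boundary_knots=(0, 10), interior_knots=(5,), intercept=False)
    with pytest.raises(SpecError):
        make_spec([0.0, 1.0], 3, "quantile")  # too few distinct values


def test_column_count_equals_df(rng):
    x = rng.normal(size=300)
    for df in (1, 2, 3, 5):
        basis = evaluate_basis(make_spec(x, df, "quantile"), x)
        assert basis.values.shape == (300, df)


def test_linear_reproduction(rng):
    x = rng.uniform(-5, 25, 400)
    basis = evaluate_basis(make_spec(x, 3, "quantile"), x).values
    design = np.column_stack([np.ones_like(x), basis])
    y = 2.0 + 3.0 * x
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    assert np.abs(y - design @ coef).max() < 1e-8


def test_linear_extrapolation_beyond_boundaries(rng):
    x = rng.uniform(0, 10, 200)
    spec = make_spec(x, 3, "quantile")
    for grid in (
        np.linspace(spec.boundary_knots[1] + 0.5, spec.boundary_knots[1] + 8, 60),
        np.linspace(spec.boundary_knots[0] - 8, spec.boundary_knots[0] - 0.5, 60),
    ):
        values = evaluate_basis(spec, grid).values
        assert np.abs(np.diff(values, n=2, axis=0)).max() < 1e-8


def test_matches_truncated_power_oracle():
    spec = make_spec(
        None, 3, "explicit", boundary_knots=(0.0, 10.0), interior_knots=(3.0, 7.0)
    )
    pts = np.array([0.5, 2.0, 4.4, 6.1, 9.5])
    ours = np.column_stack([np.ones_like(pts), evaluate_basis(spec, pts).values])
    oracle = _truncated_power_natural_basis(pts, [0.0, 3.0, 7.0, 10.0])
    # same four-dimensional function space: mutual projection is exact
    assert _span_residual(ours, oracle) < 1e-8
    assert _span_residual(oracle, ours) < 1e-8


def test_lag_rule_knots_and_degenerate_constant():
    spec = make_spec(np.arange(22), 3, "log-lag", intercept=True)
    assert spec.boundary_knots == (0.0, 21.0)
    assert np.allclose(spec.interior_knots, np.expm1(np.log1p(21.0) / 2.0))
    const = make_spec(np.arange(1), 1, "log-lag", intercept=True)
    assert const.is_constant
    assert np.all(evaluate_basis(const, [0.0, 0.0]).values == 1.0)


def test_non_finite_points_rejected(rng):
    spec = make_spec(rng.normal(size=50), 2, "quantile")
    with pytest.raises(SpecError):
        evaluate_basis(spec, [0.0, np.nan])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-3, 3, 40)
    spec = make_spec(x, 3, "quantile")
    perm = rng.permutation(40)
    direct = evaluate_basis(spec, x[perm]).values
    permuted = evaluate_basis(spec, x).values[perm]
    assert np.array_equal(direct, permuted)


def test_gcv_score_form():
    assert gcv_score(100.0, 50, 10) == pytest.approx(50 * 100.0 / 40**2)
    with pytest.raises(SpecError):
        gcv_score(1.0, 5, 5)
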