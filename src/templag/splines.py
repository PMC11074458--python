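"""Natural cubic spline bases for exposure, lag and confounder dimensions.

A natural cubic spline is piecewise cubic between its knots, twice
continuously differentiable everywhere, and constrained to be *linear*
beyond its two boundary knots.  The basis here follows the classical
regression-spline construction: a cubic B-spline basis on the knot
sequence, with the two second-derivative boundary constraints removed by
a QR projection, and (optionally) the intercept removed by dropping the
first B-spline column before projecting.  Points outside the boundary
knots are evaluated by first-order Taylor extension from the nearest
boundary, which is exact for a natural spline.

Knot-placement rules
--------------------
``quantile``  interior knots at equally spaced sample quantiles
              (type-7 linear interpolation), boundary knots at the
              observed min/max.  Default for exposure and confounders.
``log-lag``   interior knots equally spaced on log(1 + lag), boundary
              knots at 0 and the maximum lag.  Default for the lag
              dimension, whose basis carries an intercept column.
``explicit``  knots supplied by the caller.

The number of basis columns always equals ``df``:
``df = n_interior + 1 + intercept``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import SpecError

__all__ = ["SplineSpec", "BasisMatrix", "make_spec", "evaluate_basis", "gcv_score"]


@dataclass(frozen=True)
class SplineSpec:
    """Definition of a natural cubic spline basis.

    Parameters
    ----------
    df : int
        Number of basis columns.
    boundary_knots : (float, float)
        Range over which the spline is cubic; linear beyond.
    interior_knots : tuple of float
        Strictly increasing knots strictly inside the boundary.
    intercept : bool
        Whether the constant function is kept inside the basis span
        (used for the lag dimension; exposure/confounder bases leave the
        intercept to the stratum effects).
    """

    df: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = ()
    intercept: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundary_knots", tuple(float(b) for b in self.boundary_knots))
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in self.interior_knots))
        b0, b1 = self.boundary_knots
        if not (np.isfinite(b0) and np.isfinite(b1)):
            raise SpecError("boundary knots must be finite")
        if self.is_constant:
            return
        if b0 >= b1:
            raise SpecError(f"boundary knots must be increasing, got ({b0}, {b1})")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0) or ik[0] <= b0 or ik[-1] >= b1):
            raise SpecError("interior knots must be strictly increasing and strictly inside the boundary")
        expected = len(self.interior_knots) + 1 + int(self.intercept)
        if self.df != expected:
            raise SpecError(
                f"df={self.df} inconsistent with {len(self.interior_knots)} interior knots "
                f"and intercept={self.intercept} (expected df={expected})"
            )

    @property
    def is_constant(self) -> bool:
        """Single-column constant basis: df 1 with intercept (uniform lag
        weights; also the degenerate case when max lag is 0)."""
        return self.df == 1 and self.intercept and not self.interior_knots


@dataclass(frozen=True)
class BasisMatrix:
    """Realized basis columns at a set of evaluation points."""

    values: np.ndarray
    spec: SplineSpec
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.points), self.spec.df):
            raise SpecError("basis matrix shape inconsistent with spec")
        if not np.all(np.isfinite(self.values)):
            raise SpecError("basis matrix contains non-finite entries")


def make_spec(
    values,
    df: int,
    knot_rule: str = "quantile",
    *,
    intercept: bool = False,
    boundary_knots: tuple[float, float] | None = None,
    interior_knots=None,
) -> SplineSpec:
    """Build a :class:`SplineSpec` from data using a knot-placement rule.

    ``values`` is the observed sample of the variable (for ``quantile``)
    or the lag values ``0..L`` (for ``log-lag``).  With ``explicit``,
    ``boundary_knots`` and ``interior_knots`` are taken as given and
    checked against ``df``.
    """
    if df < 1:
        raise SpecError("df must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    if knot_rule == "explicit":
        if boundary_knots is None:
            raise SpecError("explicit rule requires boundary_knots")
        interior = tuple(interior_knots or ())
        return SplineSpec(df=df, boundary_knots=tuple(boundary_knots),
                          interior_knots=interior, intercept=intercept)
    if not np.all(np.isfinite(x)):
        raise SpecError("knot placement requires finite values")
    if df == 1 and intercept:
        if knot_rule == "log-lag":
            return SplineSpec(df=1, boundary_knots=(0.0, float(x.max())), intercept=True)
        return SplineSpec(df=1, boundary_knots=(float(x.min()), float(x.max())), intercept=True)
    m = df - 1 - int(intercept)
    if knot_rule == "quantile":
        if np.unique(x).size < df + 1:
            raise SpecError(f"need at least df+1={df + 1} distinct values for quantile knots")
        probs = np.linspace(0.0, 1.0, m + 2)[1:-1]
        interior = tuple(np.quantile(x, probs))  # type-7 linear interpolation
        return SplineSpec(df=df, boundary_knots=(float(x.min()), float(x.max())),
                          interior_knots=interior, intercept=intercept)
    if knot_rule == "log-lag":
        max_lag = int(round(float(x.max())))
        if max_lag == 0:
            if df == 1 and intercept:
                return SplineSpec(df=1, boundary_knots=(0.0, 0.0), interior_knots=(), intercept=True)
            raise SpecError("max lag 0 admits only the constant basis (df=1, intercept)")
        grid = np.expm1(np.linspace(0.0, np.log1p(max_lag), m + 2))[1:-1]
        return SplineSpec(df=df, boundary_knots=(0.0, float(max_lag)),
                          interior_knots=tuple(grid), intercept=intercept)
    raise SpecError(f"unknown knot rule {knot_rule!r}")


def _bspline(spec: SplineSpec) -> BSpline:
    b0, b1 = spec.boundary_knots
    t = np.concatenate([[b0] * 4, spec.interior_knots, [b1] * 4])
    n_b = len(spec.interior_knots) + 4
    return BSpline(t, np.eye(n_b), 3, extrapolate=True)

def _projector(spec: SplineSpec) -> np.ndarray:
    """Columns combining the (possibly intercept-dropped) B-spline basis
    into a natural basis: the orthogonal complement of the two
    second-derivative boundary constraints."""
    spl = _bspline(spec)
    d2 = spl.derivative(2)(np.asarray(spec.boundary_knots))  # (2, n_b)
    start = 0 if spec.intercept else 1
    d2 = d2[:, start:]
    q = np.linalg.qr(d2.T, mode="complete")[0]
    return q[:, 2:]


def evaluate_basis(spec: SplineSpec, points) -> BasisMatrix:
    """Evaluate the natural cubic spline basis at ``points``.

    Points outside the boundary knots are linearly extrapolated (value
    plus first derivative at the nearest boundary), matching the natural
    boundary behaviour.
    """
    x = np.atleast_1d(np.asarray(points, dtype=float)).ravel()
    if not np.all(np.isfinite(x)):
        raise SpecError("evaluation points must be finite")
    if spec.is_constant:
        return BasisMatrix(values=np.ones((x.size, 1)), spec=spec, points=x)
    b0, b1 = spec.boundary_knots
    spl = _bspline(spec)
    start = 0 if spec.intercept else 1
    xc = np.clip(x, b0, b1)
    vals = spl(xc)[:, start:]
    outside = (x < b0) | (x > b1)
    if np.any(outside):
        d1 = spl.derivative(1)
        slope = d1(xc[outside])[:, start:]
        vals[outside] += (x[outside] - xc[outside])[:, None] * slope
    basis = vals @ _projector(spec)
    return BasisMatrix(values=basis, spec=spec, points=x)


def gcv_score(deviance: float, n_obs: int, n_params: int) -> float:
    """Generalized cross-validation score ``n * D / (n - p)**2``.

    ``D`` is the model deviance and ``p`` the number of estimated
    non-stratum parameters.  Lower is better; used to compare candidate
    spline df choices on the same data.
    """
    if n_obs <= n_params:
        raise SpecError("GCV undefined when n_obs <= n_params")
    return n_obs * deviance / (n_obs - n_params) ** 2
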