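"""Conditional Poisson regression with time strata eliminated by profiling.

The model is a Poisson log-linear model with one free intercept per
case-crossover stratum.  Profiling the stratum intercepts out of the
likelihood yields, for each stratum s with day set T_s and total count
Y_s = sum_{t in T_s} y_t,

    l(beta) = sum_t y_t eta_t  -  sum_s Y_s log sum_{t in T_s} exp(eta_t)

which is exactly the within-stratum multinomial conditional likelihood,
so the profile MLE and its observed-information covariance coincide
with those of the dummy-variable Poisson regression (an equivalence the
test suite checks directly).  Strata whose total count is zero
contribute nothing and are dropped; the first rows of the series that
lack a complete exposure history are excluded via the cross-basis
validity mask rather than imputed.

Design columns are centered within stratum before optimization — a
pure reparameterization that leaves the likelihood, estimates and
covariance unchanged but conditions the Newton updates far better than
expanding hundreds of stratum dummies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .crossbasis import CrossBasisMatrix
from .design import ConfounderDesign, StratumIndex
from .errors import ConvergenceError, SingularDesignError, SpecError

__all__ = ["FitResult", "fit_conditional_poisson"]


@dataclass(frozen=True)
class FitResult:
    """Coefficients and covariance from a conditional Poisson fit.

    ``beta`` is on the log-rate-ratio scale over the cross-basis columns
    followed by the confounder columns; ``cov`` is the corresponding
    observed-information covariance.
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    deviance: float
    n_effective: int
    n_strata: int
    converged: bool
    n_iter: int
    column_labels: tuple[str, ...]
    n_crossbasis_columns: int
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        p = self.beta.size
        if self.cov.shape != (p, p):
            raise SpecError("covariance dimensions do not match coefficients")
        if self.deviance < -1e-8:
            raise SpecError("negative deviance")


def _as_design(part, default_label: str) -> tuple[np.ndarray, list[str], np.ndarray | None, int | None]:
    """Accept CrossBasisMatrix / ConfounderDesign / plain ndarray."""
    if part is None:
        return np.empty((0, 0)), [], None, None
    if isinstance(part, CrossBasisMatrix):
        return part.values, list(part.spec.column_labels), part.valid, part.spec.n_columns
    if isinstance(part, ConfounderDesign):
        return part.values, list(part.labels), None, None
    arr = np.asarray(part, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    labels = [f"{default_label}{i + 1}" for i in range(arr.shape[1])]
    return arr, labels, None, None


def fit_conditional_poisson(
    crossbasis,
    confounders=None,
    counts=None,
    strata: StratumIndex | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    quasipoisson: bool = False,
) -> FitResult:
    """Maximize the stratum-profiled Poisson likelihood by Newton iteration.

    Parameters
    ----------
    crossbasis : CrossBasisMatrix or array
        Exposure design columns (rows flagged invalid are dropped).
    confounders : ConfounderDesign or array, optional
        Additional adjustment columns.
    counts : array of non-negative integers
        Daily outcome counts, aligned with the design rows.
    strata : StratumIndex
        Case-crossover stratum assignment, aligned with the design rows.
    quasipoisson : bool
        If True, inflate the covariance by the Pearson dispersion
        estimate (point estimates unchanged).

    Convergence is declared when the relative log-likelihood change
    falls below ``tol`` (default 1e-10) within ``max_iter`` iterations;
    step-halving keeps the log-likelihood non-decreasing.
    """
    xb, labels_b, valid, n_cb = _as_design(crossbasis, "x")
    xc_part, labels_c, _, _ = _as_design(confounders, "z")
    if xc_part.size:
        if xc_part.shape[0] != xb.shape[0]:
            raise SpecError("cross-basis and confounder designs have different row counts")
        X = np.column_stack([xb, xc_part])
    else:
        X = xb
    labels = tuple(labels_b + labels_c)
    if n_cb is None:
        n_cb = xb.shape[1]

    y = np.asarray(counts)
    if y.shape[0] != X.shape[0]:
        raise SpecError("counts length does not match design rows")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise SpecError("counts must be non-negative integers")
    y = np.asarray(np.round(y), dtype=float)
    if strata is None:
        raise SpecError("a StratumIndex is required")
    codes = np.asarray(strata.codes)
    if codes.shape[0] != X.shape[0]:
        raise SpecError("stratum assignment length does not match design rows")

    keep = np.isfinite(X).all(axis=1)
    if valid is not None:
        keep &= valid

    Xv, yv, cv = X[keep], y[keep], codes[keep]
    order = np.argsort(cv, kind="stable")
    Xs, ys, cs = Xv[order], yv[order], cv[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(cs)) + 1])
    sizes = np.diff(np.concatenate([starts, [len(cs)]]))
    Ys = np.add.reduceat(ys, starts)

    keep_stratum = Ys > 0
    keep_row = np.repeat(keep_stratum, sizes)
    Xs, ys = Xs[keep_row], ys[keep_row]
    cs = cs[keep_row]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(cs)) + 1]) if len(cs) else np.array([0])
    sizes = np.diff(np.concatenate([starts, [len(cs)]]))
    Ys = Ys[keep_stratum]
    n_eff = int(len(ys))
    n_strata = int(len(Ys))
    p = Xs.shape[1]
    if n_eff < p:
        raise SingularDesignError(f"only {n_eff} informative days for {p} parameters")

    # center within stratum (reparameterization; likelihood unchanged)
    means = np.add.reduceat(Xs, starts, axis=0) / sizes[:, None]
    Xc = Xs - np.repeat(means, sizes, axis=0)

    scale = np.sqrt(np.mean(Xc**2, axis=0))
    if np.any(scale <= 0) or not np.all(np.isfinite(scale)):
        bad = [labels[i] for i in np.flatnonzero(~(scale > 0))]
        raise SingularDesignError(f"columns constant within every stratum: {bad}")
    sv = np.linalg.svd(Xc / scale, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-9:
        raise SingularDesignError("design is rank-deficient after stratum centering")

    rep = lambda a: np.repeat(a, sizes)

    def loglik_and_probs(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = Xc @ beta
        emax = np.maximum.reduceat(eta, starts)
        z = np.exp(eta - rep(emax))
        Z = np.add.reduceat(z, starts)
        ll = float(ys @ eta - Ys @ (emax + np.log(Z)))
        return ll, z / rep(Z)

    beta = np.zeros(p)
    ll, probs = loglik_and_probs(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = rep(Ys) * probs
        grad = Xc.T @ (ys - w)
        M = np.add.reduceat(probs[:, None] * Xc, starts, axis=0)
        H = (Xc * w[:, None]).T @ Xc - (M * Ys[:, None]).T @ M  # negative Hessian
        try:
            delta = cho_solve(cho_factor(H), grad)
        except np.linalg.LinAlgError:
            H = H + np.eye(p) * (1e-10 * np.trace(H) / p + 1e-12)
            delta = cho_solve(cho_factor(H), grad)

        step = 1.0
        for _ in range(40):
            ll_new, probs_new = loglik_and_probs(beta + step * delta)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the log-likelihood")
        beta = beta + step * delta
        change = ll_new - ll
        ll, probs = ll_new, probs_new
        if abs(change) <= tol * (abs(ll) + 0.1):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    w = rep(Ys) * probs
    M = np.add.reduceat(probs[:, None] * Xc, starts, axis=0)
    H = (Xc * w[:, None]).T @ Xc - (M * Ys[:, None]).T @ M
    cov = cho_solve(cho_factor(H), np.eye(p))
    cov = (cov + cov.T) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(ys > 0, ys * np.log(ys), 0.0).sum() - np.where(Ys > 0, Ys * np.log(Ys), 0.0).sum()
    deviance = float(max(2.0 * (sat - ll), 0.0))

    dispersion = 1.0
    if quasipoisson:
        dof = n_eff - p - n_strata
        if dof > 0:
            pearson = float(np.sum((ys - w) ** 2 / np.where(w > 0, w, np.inf)))
            dispersion = pearson / dof
            cov = cov * dispersion

    return FitResult(
        beta=beta,
        cov=cov,
        loglik=ll,
        deviance=deviance,
        n_effective=n_eff,
        n_strata=n_strata,
        converged=converged,
        n_iter=it,
        column_labels=labels,
        n_crossbasis_columns=n_cb,
        dispersion=dispersion,
    )
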