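"""Phylogenetic generalized least squares under Pagel's lambda.

Fits log-log allometries ``y = intercept + slope * x`` where the residuals
are multivariate normal with covariance ``sigma2 * C(lambda)`` and
``C(lambda)`` is the Brownian-motion tip correlation matrix of a
time-calibrated tree with its off-diagonal entries scaled by
``lambda in [0, 1]``.  ``lambda = 0`` recovers ordinary least squares,
``lambda = 1`` the standard Brownian model.  Optional per-species variance
inflation (measurement-error GLS) adds a known diagonal term, in which case
the residual variance is estimated jointly with lambda.

lambda is estimated by maximum likelihood: a coarse grid scan over [0, 1]
followed by bounded scalar refinement (tolerance 1e-6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from ._trees import brownian_vcv, is_ultrametric
from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "AllometricFit",
    "lambda_correlation",
    "pgls_fit",
    "pgls_loglik",
    "pgls_confband",
    "pgls_predict_newtip",
]


def lambda_correlation(tree, lam: float) -> tuple[list[str], np.ndarray]:
    """Tip correlation matrix under Pagel's lambda.

    Off-diagonal entries are ``lam`` times the Brownian-motion correlation
    ``t_mrca / sqrt(t_i * t_j)`` (shared-path fraction for an ultrametric
    tree); the diagonal is 1.  Returns ``(labels, C)``.
    """
    if not 0.0 <= lam <= 1.0:
        raise InvalidArgumentError(f"lambda must be in [0, 1], got {lam}")
    labels, V = brownian_vcv(tree)
    d = np.sqrt(np.diag(V))
    if np.any(d <= 0):
        raise InvalidArgumentError("tree has zero-depth tips")
    C = V / np.outer(d, d)
    C = lam * C
    np.fill_diagonal(C, 1.0)
    if not is_ultrametric(tree):
        warnings.warn("tree is not ultrametric; lambda correlation uses "
                      "generalized shared-path fractions", stacklevel=2)
    return labels, C


def _scale_offdiag(C1: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of a unit-diagonal correlation matrix."""
    C = lam * C1
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class AllometricFit:
    """Result of a lambda-GLS regression of one log10 trait on another.

    ``param_cov`` is the 2x2 covariance of ``(intercept, slope)`` from the
    GLS normal equations; ``sigma2`` the (bias-corrected) residual variance
    at the tip level; ``loglik`` the profile ML log-likelihood at
    ``lambda_hat``.
    """

    intercept: float
    slope: float
    lambda_hat: float
    sigma2: float
    param_cov: np.ndarray
    n: int
    species: list[str]
    loglik: float
    # internals needed for conditional-normal prediction at new tips
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _corr: np.ndarray = field(repr=False, default=None)
    _weights: np.ndarray = field(repr=False, default=None)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Fixed-effect (population-level) prediction on the log10 scale."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "lambda_hat": self.lambda_hat,
            "sigma2": self.sigma2,
            "param_cov": np.asarray(self.param_cov).tolist(),
            "n": self.n,
            "loglik": self.loglik,
        }


def _align(x, y, tree):
    """Intersect trait series with tree tips; returns X-vector, y, corr base."""
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    labels, V = brownian_vcv(tree)
    tip_set = set(labels)
    common = [s for s in x.index if s in tip_set and s in y.index
              and np.isfinite(x[s]) and np.isfinite(y[s])]
    dropped = [s for s in x.index if s not in tip_set]
    if dropped:
        warnings.warn(f"{len(dropped)} species not on tree were dropped: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      stacklevel=3)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >=3 species common to tree and data, got {len(common)}")
    idx = [labels.index(s) for s in common]
    Vs = V[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(Vs))
    C1 = Vs / np.outer(d, d)  # unit-diagonal Brownian correlation
    return x[common].to_numpy(), y[common].to_numpy(), C1, common


def _gls_core(X, yv, C, weights_sigma2=None):
    """GLS estimate and sufficient statistics for covariance ``C`` (or
    ``sigma2*C + diag(w)`` pre-assembled by the caller)."""
    cho = cho_factor(C, lower=True)
    Ci_X = cho_solve(cho, X)
    Ci_y = cho_solve(cho, yv)
    XtCiX = X.T @ Ci_X
    try:
        beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    except np.linalg.LinAlgError as err:
        raise DegenerateDesignError("singular design (constant x?)") from err
    resid = yv - X @ beta
    q = float(resid @ cho_solve(cho, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return beta, resid, q, logdet, XtCiX, cho


def _profile_nll(lam, X, yv, C1):
    """Negative profile log-likelihood over (beta, sigma2) at fixed lambda."""
    n = len(yv)
    C = _scale_offdiag(C1, lam)
    _, _, q, logdet, _, _ = _gls_core(X, yv, C)
    s2 = max(q / n, 1e-300)
    return 0.5 * (n * np.log(2 * np.pi * s2) + n + logdet)


def _joint_nll(lam, log_s2, X, yv, C1, w):
    """Negative log-likelihood with known diagonal variance inflation w."""
    n = len(yv)
    s2 = np.exp(log_s2)
    Sigma = s2 * _scale_offdiag(C1, lam) + np.diag(w)
    _, _, q, logdet, _, _ = _gls_core(X, yv, Sigma)
    return 0.5 * (q + logdet + n * np.log(2 * np.pi))


def _optimize_lambda(fun, tol=1e-6):
    """Minimize a scalar function over [0, 1]: coarse grid + bounded refine."""
    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([fun(g) for g in grid])
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    if hi - lo < tol:
        return float(grid[k])
    res = optimize.minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    # keep whichever endpoint/grid point is best (guards flat likelihoods)
    cand = [(vals[k], grid[k]), (res.fun, float(res.x))]
    return min(cand)[1]


def pgls_fit(x, y, tree, weights=None, lam: float | None = None) -> AllometricFit:
    """Fit ``y = intercept + slope * x`` by lambda-GLS on a tree.

    Parameters
    ----------
    x, y
        Mappings or pandas Series of log10 trait values keyed by species.
    tree
        dendropy time-calibrated tree containing the species as tips.
        Species present in the data but absent from the tree are dropped
        with a warning.
    weights
        Optional mapping/Series of per-species known variance inflation
        (e.g. within-species variance of the mean), added to the diagonal
        of the residual covariance.
    lam
        Fix Pagel's lambda at this value instead of estimating it.
    """
    if lam is not None and not 0.0 <= lam <= 1.0:
        raise InvalidArgumentError(f"lambda must be in [0, 1], got {lam}")
    xv, yv, C1, common = _align(x, y, tree)
    n = len(yv)
    if np.ptp(xv) == 0:
        raise DegenerateDesignError("predictor is constant")
    X = np.column_stack([np.ones(n), xv])

    if weights is None:
        if lam is None:
            lam_hat = _optimize_lambda(lambda g: _profile_nll(g, X, yv, C1))
        else:
            lam_hat = float(lam)
        C = _scale_offdiag(C1, lam_hat)
        beta, resid, q, logdet, XtCiX, _ = _gls_core(X, yv, C)
        s2_ml = q / n
        loglik = -0.5 * (n * np.log(2 * np.pi * max(s2_ml, 1e-300)) + n + logdet)
        sigma2 = q / (n - 2)  # bias-corrected for the 2 regression params
        param_cov = sigma2 * np.linalg.inv(XtCiX)
        wvec = None
    else:
        wser = pd.Series(weights, dtype=float)
        wvec = np.array([max(float(wser.get(s, 0.0)), 0.0) for s in common])
        # rough starting variance from OLS residuals
        b0 = np.linalg.lstsq(X, yv, rcond=None)[0]
        s2_init = max(float(np.var(yv - X @ b0)), 1e-8)

        def best_s2(g):
            r = optimize.minimize_scalar(
                lambda ls: _joint_nll(g, ls, X, yv, C1, wvec),
                bracket=(np.log(s2_init) - 2, np.log(s2_init) + 2))
            return r.fun, float(r.x)

        if lam is None:
            lam_hat = _optimize_lambda(lambda g: best_s2(g)[0])
        else:
            lam_hat = float(lam)
        nll, log_s2 = best_s2(lam_hat)
        sigma2 = float(np.exp(log_s2))
        Sigma = sigma2 * _scale_offdiag(C1, lam_hat) + np.diag(wvec)
        beta, resid, q, logdet, XtSiX, _ = _gls_core(X, yv, Sigma)
        loglik = -nll
        param_cov = np.linalg.inv(XtSiX)

    return AllometricFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        lambda_hat=float(lam_hat), sigma2=float(max(sigma2, 0.0)),
        param_cov=param_cov, n=n, species=list(common), loglik=float(loglik),
        _x=xv, _y=yv, _corr=_scale_offdiag(C1, lam_hat), _weights=wvec,
    )


def pgls_loglik(x, y, tree, lam: float, weights=None) -> float:
    """Profile ML log-likelihood of the regression at a fixed lambda."""
    return pgls_fit(x, y, tree, weights=weights, lam=lam).loglik


def pgls_confband(fit: AllometricFit, x_grid, level: float = 0.95,
                  include_residual: bool = False):
    """Pointwise confidence band for the regression line.

    By default the band reflects parameter uncertainty only (a band for the
    fitted mean); ``include_residual=True`` adds the residual variance,
    giving a prediction-style band.  Returns ``(fitted, lower, upper)``.
    """
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError(f"level must be in (0, 1), got {level}")
    xg = np.asarray(x_grid, dtype=float)
    z = norm.ppf(0.5 + level / 2.0)
    X0 = np.column_stack([np.ones(xg.shape[0]), xg])
    var = np.einsum("ij,jk,ik->i", X0, fit.param_cov, X0)
    if include_residual:
        var = var + fit.sigma2
    fitted = fit.predict(xg)
    half = z * np.sqrt(np.maximum(var, 0.0))
    return fitted, fitted - half, fitted + half


def pgls_predict_newtip(fit: AllometricFit, tree_with_new_tip, new_tip: str,
                        x_new: float) -> tuple[float, float]:
    """Conditional-normal prediction of the response at a new tip.

    The new tip must be attached to a tree that also carries every species
    used in the fit.  The prediction combines the fixed-effect line with a
    covariance-weighted adjustment toward the residuals of phylogenetically
    close species (universal-kriging form); the variance includes the
    residual term, the reduction from conditioning, and parameter
    uncertainty.
    """
    labels, V = brownian_vcv(tree_with_new_tip)
    pos = {s: i for i, s in enumerate(labels)}
    if new_tip not in pos:
        raise InvalidArgumentError(f"new tip {new_tip!r} not on tree")
    missing = [s for s in fit.species if s not in pos]
    if missing:
        raise InvalidArgumentError(
            f"fit species missing from tree: {missing[:5]}")
    d = np.sqrt(np.diag(V))
    Cfull = V / np.outer(d, d)
    ridx = [pos[s] for s in fit.species]
    nidx = pos[new_tip]
    lam = fit.lambda_hat
    Crr = _scale_offdiag(Cfull[np.ix_(ridx, ridx)], lam)
    v = lam * Cfull[nidx, ridx]

    s2 = fit.sigma2
    w = fit._weights if fit._weights is not None else np.zeros(len(ridx))
    Sigma = s2 * Crr + np.diag(w)
    c = s2 * v
    cho = cho_factor(Sigma, lower=True)
    Si_c = cho_solve(cho, c)
    X = np.column_stack([np.ones(len(ridx)), fit._x])
    resid = fit._y - X @ np.array([fit.intercept, fit.slope])
    mean = fit.intercept + fit.slope * x_new + float(Si_c @ resid)
    x0 = np.array([1.0, x_new])
    dvec = x0 - X.T @ Si_c
    var = s2 - float(c @ Si_c) + float(dvec @ fit.param_cov @ dvec)
    return float(mean), float(max(var, 0.0))
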