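"""Maximum-likelihood fitting of single structural equations.

Two families are supported, matching the node types of the path model:

* ``gaussian`` — identity link, closed-form least squares.  The reported
  log-likelihood uses the ML variance estimate (divisor ``n``) so that
  likelihood-ratio tests and information criteria are likelihood-consistent;
  standard errors use the conventional unbiased variance (divisor ``n - p``).
* ``logit`` — Bernoulli likelihood maximized by iteratively reweighted least
  squares (Newton scoring) with step-halving, which makes the log-likelihood
  non-decreasing across iterations (asserted).  Convergence when the maximum
  absolute score drops below 1e-8 or the relative log-likelihood change below
  1e-10.  Separation raises :class:`SeparationError` instead of returning a
  silently divergent fit; an optional ridge penalty exists as a fallback for
  bootstrap replicates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)

GAUSSIAN = "gaussian"
LOGIT = "logit"
FAMILIES = (GAUSSIAN, LOGIT)

SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
SEPARATION_BETA = 15.0


@dataclass
class DesignMatrix:
    """Response + named predictor matrix for one equation.

    The intercept column, when present, is always first.  Binary responses
    must be coded 0/1.  No missing entries are permitted (complete-case
    filtering happens upstream).
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    family: str

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X must be 2-d with one row per response element")
        if len(self.columns) != self.X.shape[1]:
            raise ValidationError("column names do not match design width")
        if not np.isfinite(self.y).all() or not np.isfinite(self.X).all():
            raise ValidationError("design matrix contains missing or non-finite entries")
        if self.family == LOGIT and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValidationError("binary responses must be coded 0/1")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def design_from_frame(frame: pd.DataFrame, response: str, predictors: list[str],
                      family: str, add_intercept: bool = True) -> DesignMatrix:
    cols = (["intercept"] if add_intercept else []) + list(predictors)
    mats = ([np.ones(len(frame))] if add_intercept else []) + [
        frame[c].to_numpy(dtype=float) for c in predictors
    ]
    return DesignMatrix(frame[response].to_numpy(dtype=float), np.column_stack(mats), cols, family)


@dataclass
class EquationFit:
    """One fitted equation: named coefficients on the linear-predictor scale."""

    name: str
    family: str
    params: pd.Series
    se: pd.Series
    cov: np.ndarray
    loglik: float
    scale: float | None  # ML residual variance (gaussian only)
    n: int
    n_params: int  # all estimated parameters, incl. gaussian variance
    n_iter: int
    grad_norm: float
    ridge: float = 0.0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n)

    def zvalues(self) -> pd.Series:
        return self.params / self.se

    def pvalues(self) -> pd.Series:
        z = self.zvalues()
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)


def check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    """Raise :class:`RankDeficiencyError` naming the collinear columns."""
    if X.shape[1] == 0:
        return
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = (d.max() if d.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(columns[i] for i in piv[rank:])
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


def fit_gaussian(design: DesignMatrix, name: str = "", check_rank: bool = True) -> EquationFit:
    """Ordinary least squares = Gaussian-identity maximum likelihood."""
    if design.family != GAUSSIAN:
        raise ValidationError(f"fit_gaussian got family {design.family!r}")
    n, p = design.n, design.p
    if n <= p:
        raise ValidationError(f"equation {name!r}: need n > number of predictors ({n} <= {p})")
    if check_rank:
        check_full_rank(design.X, design.columns)
    beta, _, _, _ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta
    rss = float(resid @ resid)
    scale_ml = rss / n
    s2 = max(scale_ml, np.finfo(float).tiny)
    loglik = -0.5 * n * np.log(2.0 * np.pi * s2) - 0.5 * rss / s2
    xtx_inv = np.linalg.inv(design.X.T @ design.X)
    s2_unbiased = rss / (n - p)
    cov = xtx_inv * s2_unbiased
    se = np.sqrt(np.diag(cov))
    return EquationFit(
        name=name, family=GAUSSIAN,
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        cov=cov, loglik=float(loglik), scale=scale_ml,
        n=n, n_params=p + 1, n_iter=1, grad_norm=0.0,
    )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), numerically stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(design: DesignMatrix, name: str = "", max_iter: int = 100,
                 ridge: float = 0.0, check_rank: bool = True) -> EquationFit:
    """Bernoulli-logit ML via IRLS with monotone step-halving.

    ``ridge`` > 0 adds a quadratic penalty on the non-intercept coefficients;
    it is intended only as a logged fallback for bootstrap replicates where
    resampling occasionally induces separation.
    """
    if design.family != LOGIT:
        raise ValidationError(f"fit_logistic got family {design.family!r}")
    y, X = design.y, design.X
    n, p = design.n, design.p
    if y.min() == y.max():
        raise ValidationError(f"equation {name!r}: response takes a single value; both classes required")
    if check_rank:
        check_full_rank(X, design.columns)

    pen = np.full(p, ridge)
    if design.columns and design.columns[0] == "intercept":
        pen[0] = 0.0

    def penalized_ll(beta):
        return _bernoulli_loglik(y, X @ beta) - 0.5 * float(pen @ (beta * beta))

    beta = np.zeros(p)
    ll = penalized_ll(beta)
    n_iter = 0
    grad_norm = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        score = X.T @ (y - mu) - pen * beta
        grad_norm = float(np.abs(score).max())
        if grad_norm < SCORE_TOL:
            converged = True
            break
        w = mu * (1.0 - mu) + 1e-12
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        delta = np.linalg.solve(hess, score)
        step = 1.0
        ll_new = None
        for _ in range(40):
            cand = beta + step * delta
            ll_cand = penalized_ll(cand)
            if ll_cand >= ll - 1e-12:
                beta, ll_new = cand, ll_cand
                break
            step *= 0.5
        if ll_new is None:
            raise ConvergenceError(
                f"equation {name!r}: step-halving could not improve the log-likelihood"
            )
        # monotonicity guarantee of the damped IRLS iteration
        assert ll_new >= ll - 1e-8, "log-likelihood decreased across IRLS iterations"
        if abs(ll_new - ll) <= LOGLIK_RTOL * (abs(ll) + LOGLIK_RTOL):
            ll = ll_new
            converged = True
            break
        ll = ll_new
        if np.abs(beta).max() > SEPARATION_BETA:
            score = X.T @ (y - special.expit(X @ beta)) - pen * beta
            grad_norm = float(np.abs(score).max())
            if grad_norm > 1e-6:
                raise SeparationError(
                    f"equation {name!r}: coefficients diverging (max |beta| > "
                    f"{SEPARATION_BETA}) with non-vanishing gradient; data are separated"
                )
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"equation {name!r}: IRLS did not converge in {max_iter} iterations")

    eta = X @ beta
    mu = special.expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    hess = (X * w[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return EquationFit(
        name=name, family=LOGIT,
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        cov=cov, loglik=_bernoulli_loglik(y, eta), scale=None,
        n=n, n_params=p, n_iter=n_iter, grad_norm=grad_norm, ridge=ridge,
    )


def fit_equation(design: DesignMatrix, name: str = "", **kwargs) -> EquationFit:
    """Dispatch on the design's family tag."""
    if design.family == GAUSSIAN:
        kwargs.pop("ridge", None)
        return fit_gaussian(design, name=name, **kwargs)
    return fit_logistic(design, name=name, **kwargs)


def information_criteria(fit: EquationFit) -> tuple[float, float]:
    """(AIC, BIC) with ``p`` counting every estimated parameter."""
    if fit.n_params <= 0:
        raise ValidationError("cannot compute information criteria for a fit with no parameters")
    return fit.aic, fit.bic


def likelihood_ratio_test(null_fit: EquationFit, alt_fit: EquationFit) -> tuple[float, int, float]:
    """LRT of a nested pair fitted on identical data.

    Returns ``(statistic, df, p)`` with the statistic clipped at zero (tiny
    negative values are numerical noise; larger ones indicate non-nesting and
    raise).
    """
    if null_fit.n != alt_fit.n:
        raise ValidationError("likelihood ratio test requires fits on the same n")
    if null_fit.family != alt_fit.family:
        raise ValidationError("likelihood ratio test requires the same family")
    if not set(null_fit.params.index) <= set(alt_fit.params.index):
        raise ValidationError("null model predictors are not a subset of the alternative's")
    df = alt_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValidationError("alternative must have strictly more parameters than the null")
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -1e-6:
        raise ValidationError("log-likelihood decreased under the alternative; models are not nested")
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))
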