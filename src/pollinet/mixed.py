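"""Mixed-effects component models: gaussian LMMs and Poisson GLMMs.

Both families carry a single normal random intercept for island identity and
are fitted by maximum likelihood (never REML) so that likelihood-based
quantities are comparable across models during path selection.

Gaussian responses go through :class:`statsmodels` ``MixedLM``.  Poisson
responses use an in-house random-intercept GLMM whose marginal likelihood is
integrated by adaptive Gauss-Hermite quadrature: with a single intercept the
per-group integrand is log-concave with closed-form derivatives, so the
posterior mode and curvature that centre the quadrature rule come from a few
Newton steps, and eleven nodes give likelihoods accurate far beyond the
tolerances used here.  Standard errors are Wald, from the numerical Hessian
of the marginal log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.tools import numdiff

GAUSSIAN = "gaussian"
POISSON = "poisson"


class FitError(RuntimeError):
    """A component model failed to converge or was degenerate."""


@dataclass
class MixedFit:
    """A fitted random-intercept model (fixed effects + variance components)."""

    family: str
    params: pd.Series           # fixed effects, "Intercept" first
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    k_params: int               # fixed effects + variance components
    re_sd: float                # random-intercept s.d.
    fitted: np.ndarray = field(repr=False, default=None)  # conditional scale of y
    converged: bool = True


def _design(x: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = ["Intercept"] + list(x.columns)
    mat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    return mat, names


def _check_predictors(x: pd.DataFrame) -> None:
    for col in x.columns:
        if float(np.std(x[col].to_numpy(dtype=float))) == 0.0:
            raise FitError(f"zero-variance predictor {col!r}")


def fit_gaussian(y: np.ndarray, x: pd.DataFrame, groups: np.ndarray) -> MixedFit:
    """ML linear mixed model with a random intercept per group.

    With a single random intercept the likelihood profiles analytically:
    given the variance ratio lambda = var_u / var_e the fixed effects are a
    one-shot GLS solve and the residual variance has a closed form, leaving
    a 1-D bounded optimisation over ln(lambda).  The lambda = 0 boundary is
    evaluated explicitly, so variance collapse degenerates cleanly to OLS.
    Wald standard errors condition on the estimated variance ratio, the
    same convention as lme4 and statsmodels.
    """
    _check_predictors(x)
    y = np.asarray(y, dtype=float)
    if float(np.std(y)) == 0.0:
        raise FitError("response has zero variance")
    exog, names = _design(x)
    n, p = exog.shape

    order = np.argsort(np.asarray(groups), kind="stable")
    xs, ys = exog[order], y[order]
    g = np.asarray(groups)[order]
    starts = np.sort(np.unique(g, return_index=True)[1])
    sizes = np.diff(np.append(starts, n)).astype(float)

    xtx = xs.T @ xs
    xty = xs.T @ ys
    yty = float(ys @ ys)
    sx = np.add.reduceat(xs, starts, axis=0)            # per-group column sums
    sy = np.add.reduceat(ys, starts)

    def profile(lam: float):
        c = lam / (1.0 + sizes * lam)                   # per-group shrinkage
        xwx = xtx - (sx * c[:, None]).T @ sx
        xwy = xty - sx.T @ (c * sy)
        ywy = yty - float(c @ sy**2)
        try:
            beta = np.linalg.solve(xwx, xwy)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"gaussian mixed model: singular design ({exc})")
        rss = max(ywy - float(beta @ xwy), 1e-300)
        sigma_e2 = rss / n
        neg2ll = (n * np.log(2 * np.pi * sigma_e2) + n
                  + float(np.log1p(sizes * lam).sum()))
        return neg2ll, beta, sigma_e2, xwx

    def objective(t: float) -> float:
        return profile(np.exp(t))[0]

    res = optimize.minimize_scalar(objective, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    neg2ll, beta, sigma_e2, xwx = profile(lam)
    neg2ll0, beta0, sigma_e20, xwx0 = profile(0.0)
    if neg2ll0 <= neg2ll:                               # boundary optimum
        lam, neg2ll, beta, sigma_e2, xwx = 0.0, neg2ll0, beta0, sigma_e20, xwx0

    cov = sigma_e2 * np.linalg.inv(xwx)
    bse = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    pvals = 2 * stats.norm.sf(np.abs(beta / bse))

    # conditional fitted values: fixed part + BLUP of the group intercept
    resid_sum = sy - sx @ beta
    blup = (lam / (1.0 + sizes * lam)) * resid_sum
    codes = pd.factorize(np.asarray(groups), sort=True)[0]
    fitted = exog @ beta + blup[codes]

    return MixedFit(
        family=GAUSSIAN,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        llf=-0.5 * neg2ll,
        k_params=len(names) + 2,            # + RE variance + residual variance
        re_sd=float(np.sqrt(lam * sigma_e2)),
        fitted=np.asarray(fitted),
        converged=True,
    )


class _PoissonGLMM:
    """Marginal likelihood machinery for the Poisson random-intercept model."""

    N_NODES = 11

    def __init__(self, y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
        order = np.argsort(np.asarray(groups), kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.exog = np.asarray(exog, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        self.starts = np.sort(starts)
        self.const = -float(special.gammaln(self.y + 1).sum())
        nodes, weights = np.polynomial.hermite.hermgauss(self.N_NODES)
        self.nodes = nodes
        self.logw = np.log(weights)

    def _group_terms(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eta = np.clip(self.exog @ beta, -30, 30)
        t = np.add.reduceat(np.exp(eta), self.starts)          # sum e^eta per group
        ysum = np.add.reduceat(self.y, self.starts)
        c = np.add.reduceat(self.y * eta, self.starts)
        return t, ysum, c

    def _quadrature(self, beta: np.ndarray, log_sigma: float):
        sigma = np.exp(log_sigma)
        t, ysum, c = self._group_terms(beta)
        inv_v = 1.0 / sigma**2
        # posterior mode of the group intercept: Newton on a concave 1-D target
        b = np.zeros_like(t)
        for _ in range(40):
            eb = np.exp(np.clip(b, -30, 30))
            grad = ysum - t * eb - b * inv_v
            hess = -t * eb - inv_v
            step = grad / hess
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        b = np.clip(b, -30, 30)
        tau = 1.0 / np.sqrt(t * np.exp(b) + inv_v)
        # adaptive nodes b_gk = b_g + sqrt(2) tau_g x_k
        bk = np.clip(b[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :],
                     -30, 30)
        h = (c[:, None] + bk * ysum[:, None] - np.exp(bk) * t[:, None]
             - 0.5 * bk**2 * inv_v)
        lw = self.logw[None, :] + self.nodes[None, :] ** 2 + h
        lse = special.logsumexp(lw, axis=1)
        ll = float((np.log(np.sqrt(2.0) * tau) + lse
                    - np.log(sigma * np.sqrt(2 * np.pi))).sum() + self.const)
        return ll, t, bk, lw, lse, inv_v

    def loglik(self, beta: np.ndarray, log_sigma: float) -> float:
        return self._quadrature(beta, log_sigma)[0]

    def loglik_grad(self, beta: np.ndarray, log_sigma: float) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood and its gradient in (beta, log sigma).

        The gradient is the posterior expectation of the complete-data score,
        evaluated on the same adaptive quadrature grid, so it matches the
        likelihood to quadrature accuracy.
        """
        ll, t, bk, lw, lse, inv_v = self._quadrature(beta, log_sigma)
        wt = np.exp(lw - lse[:, None])                 # posterior node weights
        eta = np.clip(self.exog @ beta, -30, 30)
        ex = np.exp(eta)[:, None] * self.exog
        ex_g = np.add.reduceat(ex, self.starts, axis=0)            # G x p
        xty_g = np.add.reduceat(self.y[:, None] * self.exog, self.starts, axis=0)
        s_g = (wt * np.exp(bk)).sum(axis=1)                        # E[e^b | data]
        grad_beta = (xty_g - s_g[:, None] * ex_g).sum(axis=0)
        grad_ls = float((wt * (bk**2 * inv_v - 1.0)).sum())
        return ll, np.concatenate([grad_beta, [grad_ls]])


def fit_poisson(y: np.ndarray, x: pd.DataFrame, groups: np.ndarray) -> MixedFit:
    """ML Poisson GLMM (log link) with a random intercept per group."""
    _check_predictors(x)
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise FitError("poisson response must hold non-negative integers")
    if float(np.std(y)) == 0.0:
        raise FitError("response has zero variance")
    exog, names = _design(x)
    glmm = _PoissonGLMM(y, exog, groups)
    p = exog.shape[1]

    # start from the fixed-effects Poisson GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.GLM(y, exog, family=sm.families.Poisson()).fit().params
        except Exception:
            beta0 = np.zeros(p)
            beta0[0] = np.log(max(y.mean(), 0.1))
    x0 = np.concatenate([np.asarray(beta0), [np.log(0.3)]])

    def neg(theta: np.ndarray) -> float:
        val = glmm.loglik(theta[:p], theta[p])
        return -val if np.isfinite(val) else 1e12

    def neg_with_grad(theta: np.ndarray):
        val, grad = glmm.loglik_grad(theta[:p], theta[p])
        if not np.isfinite(val):
            return 1e12, np.zeros_like(theta)
        return -val, -grad

    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(5.0))]
    res = optimize.minimize(neg_with_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": 400, "ftol": 1e-11})
    if not np.isfinite(res.fun):
        raise FitError("poisson mixed model: non-finite log-likelihood")
    theta = res.x
    llf = -float(res.fun)

    hess = numdiff.approx_hess1(theta, neg)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    var = np.diag(cov)[:p].copy()
    bad = ~np.isfinite(var) | (var <= 0)
    if bad.any():
        # fall back to the beta-block curvature with sigma held fixed
        hess_b = numdiff.approx_hess1(theta[:p], lambda b: neg(np.concatenate([b, theta[p:]])))
        var_b = np.diag(np.linalg.pinv(hess_b))
        var[bad] = var_b[bad]
    bse = np.sqrt(np.clip(var, 1e-300, None))
    z = theta[:p] / bse
    pvals = 2 * stats.norm.sf(np.abs(z))

    sigma = float(np.exp(theta[p]))
    # conditional fitted values on the count scale, using posterior modes
    t, ysum, _ = glmm._group_terms(theta[:p])
    inv_v = 1.0 / sigma**2
    b = np.zeros_like(t)
    for _ in range(40):
        eb = np.exp(np.clip(b, -30, 30))
        b -= (ysum - t * eb - b * inv_v) / (-t * eb - inv_v)
    codes = pd.factorize(np.asarray(groups), sort=True)[0]
    eta = np.clip(exog @ theta[:p], -30, 30)
    fitted = np.exp(eta + np.clip(b, -30, 30)[codes])

    return MixedFit(
        family=POISSON,
        params=pd.Series(theta[:p], index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        llf=llf,
        k_params=p + 1,
        re_sd=sigma,
        fitted=fitted,
        converged=bool(res.success),
    )


def fit_mixed(y, x: pd.DataFrame, groups, family: str) -> MixedFit:
    """Dispatch to the gaussian or Poisson random-intercept fitter."""
    if family == GAUSSIAN:
        return fit_gaussian(y, x, groups)
    if family == POISSON:
        return fit_poisson(y, x, groups)
    raise ValueError(f"unknown family {family!r}")
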