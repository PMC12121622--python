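"""Single-distribution regressions: logistic, Poisson, NB2, generalized Poisson.

These are the "standard" analyses a polyp-count outcome usually receives:
logistic regression on the dichotomized outcome (any polyp vs none) and
log-link count regressions on the raw counts.  The robust-Poisson (RP)
variant is an ordinary Poisson fit whose variance is replaced by the
Huber–White sandwich estimator.

All fits are direct maximum likelihood with analytic gradients; dispersion
parameters are handled on transformed scales (NB2 alpha on the log scale to
enforce positivity).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

from . import families as fam
from .data import AnalysisDataset
from .model import (ConvergenceError, FittedModel, SeparationError,
                    maximize_loglik, numerical_hessian)

__all__ = ["fit_logistic", "fit_count_glm", "sandwich_vcov"]

_ALPHA_FLOOR = 1e-10
_ALPHA_BOUNDARY = 1e-8


def _model_vcov(negll_grad, params):
    A = numerical_hessian(lambda v: negll_grad(v)[1], params)
    return np.linalg.pinv(A)


def sandwich_vcov(model: FittedModel, data: AnalysisDataset | None = None) -> np.ndarray:
    """Huber–White sandwich covariance ``A^{-1} B A^{-1}``.

    ``A`` is the observed information (Hessian of the negative
    log-likelihood) and ``B = sum_i s_i s_i'`` the outer product of
    per-subject scores, both evaluated at the MLE.  Valid when the mean
    model is right but the variance model is not (e.g. overdispersed counts
    fit by Poisson).
    """
    if model.score_obs_fn is None or model.negll_grad_fn is None:
        raise ValueError("model does not carry per-subject score information")
    S = model.score_obs_fn(model.params)
    A = numerical_hessian(lambda v: model.negll_grad_fn(v)[1], model.params)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "observed information is singular; check design-matrix rank"
        ) from err
    B = S.T @ S
    V = Ainv @ B @ Ainv
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _logistic_machinery(X: np.ndarray, z: np.ndarray):
    def negll_grad(b):
        eta = X @ b
        # log-lik: z*eta - log(1 + e^eta), stable via logaddexp
        ll = z * eta - np.logaddexp(0.0, eta)
        p = expit(eta)
        return -np.sum(ll), -(X.T @ (z - p))

    def loglik_obs(b):
        eta = X @ b
        return z * eta - np.logaddexp(0.0, eta)

    def score_obs(b):
        return (z - expit(X @ b))[:, None] * X

    return negll_grad, loglik_obs, score_obs


def fit_logistic(data: AnalysisDataset, design: str = "count") -> FittedModel:
    """Logistic regression of any-polyp (y > 0) on the design covariates.

    Exponentiated coefficients are odds ratios for polyp detection.  Perfect
    separation raises :class:`SeparationError` naming the offending column.
    """
    Xdf = data.count_design if design == "count" else data.inflate_design
    X = Xdf.to_numpy(dtype=float)
    z = data.binary_outcome().astype(float)
    negll_grad, loglik_obs, score_obs = _logistic_machinery(X, z)
    b0 = np.zeros(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bhat, converged = maximize_loglik(negll_grad, b0, "logistic")
    # under separation the likelihood is maximized at infinity; the gradient
    # underflows to zero long before that, so test the estimate itself
    if np.max(np.abs(bhat)) > 15.0:
        j = int(np.argmax(np.abs(bhat)))
        raise SeparationError(
            f"perfect separation suspected on column {Xdf.columns[j]!r}"
        )
    vcov = _model_vcov(negll_grad, bhat)
    return FittedModel(
        kind="LR", family=None, params=bhat, names=list(Xdf.columns),
        n_count=X.shape[1], n_inflate=0, has_dispersion=False,
        vcov=vcov, robust=False, loglik=float(np.sum(loglik_obs(bhat))),
        loglik_obs=loglik_obs(bhat), n_obs=len(z), converged=converged,
        score_obs_fn=score_obs, negll_grad_fn=negll_grad,
        fit_spec={"fitter": "logistic", "design": design},
    )


# ---------------------------------------------------------------------------
# count GLMs
# ---------------------------------------------------------------------------

def _count_machinery(family: str, X: np.ndarray, y: np.ndarray):
    """negll/grad closures over params = [beta, (internal dispersion)].

    NB2: internal dispersion is log(alpha).  GP: delta is raw, with an
    infinite barrier outside the admissible region.
    """
    p = X.shape[1]
    has_disp = family in ("negbin", "genpoisson")

    def unpack(theta):
        beta = theta[:p]
        if not has_disp:
            return beta, 0.0
        if family == "negbin":
            return beta, max(float(np.exp(theta[p])), _ALPHA_FLOOR)
        return beta, float(theta[p])

    def valid(mu, disp):
        if family != "genpoisson":
            return True
        if disp >= 1.0:
            return False
        return np.all(mu * (1.0 - disp) + disp * y > 0) and np.all(mu * (1 - disp) > 0)

    def negll_grad(theta):
        beta, disp = unpack(theta)
        xb = X @ beta
        mu = np.exp(np.clip(xb, -500, 500))
        if not valid(mu, disp):
            return np.inf, np.zeros_like(theta)
        ll = fam.log_pmf_arr(family, y, mu, disp)
        if not np.all(np.isfinite(ll)):
            return np.inf, np.zeros_like(theta)
        g_beta = X.T @ fam.dlog_pmf_dlogmu(family, y, mu, disp)
        if has_disp:
            gd = np.sum(fam.dlog_pmf_ddisp(family, y, mu, disp))
            if family == "negbin":
                gd *= disp  # chain rule to log(alpha)
            grad = np.concatenate([g_beta, [gd]])
        else:
            grad = g_beta
        return -float(np.sum(ll)), -grad

    def loglik_obs(theta):
        beta, disp = unpack(theta)
        mu = np.exp(X @ beta)
        return fam.log_pmf_arr(family, y, mu, disp)

    def score_obs(theta):
        beta, disp = unpack(theta)
        mu = np.exp(X @ beta)
        s = fam.dlog_pmf_dlogmu(family, y, mu, disp)[:, None] * X
        if has_disp:
            sd = fam.dlog_pmf_ddisp(family, y, mu, disp)
            if family == "negbin":
                sd = sd * disp
            s = np.hstack([s, sd[:, None]])
        return s

    return unpack, negll_grad, loglik_obs, score_obs


_KIND_BY_FAMILY = {"poisson": "PR", "negbin": "NB", "genpoisson": "GP"}


def fit_count_glm(data: AnalysisDataset, family: str = "poisson",
                  robust: bool = False) -> FittedModel:
    """Log-link count regression of polyp counts on the count design.

    Exponentiated coefficients are risk ratios for the expected polyp
    count.  ``robust=True`` replaces the model-based covariance with the
    sandwich estimator (the RP analysis); point estimates are unchanged.
    For NB2 / GP a dispersion parameter is estimated jointly; an NB2
    dispersion pinned at the zero boundary is reported as 0 with a warning.
    """
    if family not in fam.FAMILY_NAMES:
        raise ValueError(f"family must be one of {fam.FAMILY_NAMES}")
    Xdf = data.count_design
    X = Xdf.to_numpy(dtype=float)
    y = data.outcome.astype(float)

    unpack, negll_grad, loglik_obs, score_obs = _count_machinery(family, X, y)

    # Poisson start: intercept at log(mean), refined by its own BFGS pass
    beta_start = np.zeros(X.shape[1])
    beta_start[0] = np.log(max(y.mean(), 1e-3))
    if family == "poisson":
        theta0 = beta_start
    else:
        pois = fit_count_glm(data, "poisson")
        ybar, s2 = y.mean(), y.var()
        if family == "negbin":
            a0 = max((s2 - ybar) / max(ybar**2, 1e-8), 0.01)
            theta0 = np.concatenate([pois.count_coefficients, [np.log(a0)]])
        else:
            theta0 = np.concatenate([pois.count_coefficients, [0.01]])

    theta, converged = maximize_loglik(negll_grad, theta0, f"{family} GLM")
    if not converged:
        g = negll_grad(theta)[1]
        raise ConvergenceError(
            f"{family} regression did not converge; last |grad| = {np.max(np.abs(g)):.3g}"
        )

    dispersion = None
    names = list(Xdf.columns)
    if family == "negbin":
        alpha = float(np.exp(theta[-1]))
        if alpha < _ALPHA_BOUNDARY:
            warnings.warn("NB2 dispersion at the zero boundary; reporting alpha = 0")
            alpha = 0.0
        dispersion = alpha
        names = names + ["log_alpha"]
    elif family == "genpoisson":
        dispersion = float(theta[-1])
        names = names + ["delta"]

    vcov = _model_vcov(negll_grad, theta)
    kind = _KIND_BY_FAMILY[family]
    model = FittedModel(
        kind=("RP" if (robust and family == "poisson") else kind),
        family=family, params=theta, names=names,
        n_count=X.shape[1], n_inflate=0,
        has_dispersion=family != "poisson",
        vcov=vcov, robust=False, loglik=float(np.sum(loglik_obs(theta))),
        loglik_obs=loglik_obs(theta), n_obs=len(y), converged=converged,
        dispersion=dispersion, score_obs_fn=score_obs, negll_grad_fn=negll_grad,
        fit_spec={"fitter": "count_glm", "family": family, "robust": robust},
    )
    if robust:
        model.vcov = sandwich_vcov(model)
        model.robust = True
    return model
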