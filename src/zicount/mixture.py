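"""Zero-inflated and hurdle models for zero-heavy polyp counts.

A zero-inflated model is a two-part mixture: with probability ``pi_i`` a
subject is a *structural* zero (genuinely no polyps, or none that the count
process could produce), and with probability ``1 - pi_i`` the outcome is
drawn from a full count distribution — which can itself emit zeros
(*sampling* zeros: polyps present but missed at colonoscopy).

    P(Y = 0) = pi + (1 - pi) f(0)
    P(Y = y) = (1 - pi) f(y),        y > 0

The inflation part models the odds of a structural ("excess") zero on the
logit scale, so an exponentiated inflation coefficient below 1 means the
exposed group has *fewer* structural zeros; because odds ratios are
symmetric, its inverse reads as the effect on having detectable polyps.

A hurdle model instead routes *all* zeros through a logistic part and
models positives with a zero-truncated count distribution:

    P(Y = 0) = 1 - pi_pos
    P(Y = y) = pi_pos * f(y) / (1 - f(0)),   y > 0

Both are fit by direct joint maximization of the observed-data likelihood
with analytic gradients (no EM), which gives one code path for the sandwich
variance used by the ZIRP analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import families as fam
from .data import AnalysisDataset
from .glm import fit_count_glm, fit_logistic, sandwich_vcov
from .model import (ConvergenceError, FittedModel, InstabilityError,
                    maximize_loglik, numerical_hessian)

__all__ = ["fit_zero_inflated", "fit_hurdle", "predict_components", "MixturePrediction"]

_ALPHA_FLOOR = 1e-10

ZI_KINDS = {"poisson": "ZIP", "negbin": "ZINB", "genpoisson": "ZIGP"}
HURDLE_KINDS = {"poisson": "ZHP", "negbin": "ZHNB", "genpoisson": "ZHGP"}


@dataclass
class MixturePrediction:
    """Per-subject component predictions from a two-part (or one-part) fit."""

    pi: np.ndarray                 # structural-zero probability (hurdle: P(Y=0))
    mu: np.ndarray                 # count-component mean
    prob_zero: np.ndarray          # total P(Y = 0)
    prob_pos: np.ndarray           # P(Y > 0)
    expected_count: np.ndarray     # E[Y]
    structural_posterior: np.ndarray  # P(structural | Y = 0)


def _unpack_disp(family: str, theta, idx):
    if family == "negbin":
        return max(float(np.exp(theta[idx])), _ALPHA_FLOOR)
    if family == "genpoisson":
        return float(theta[idx])
    return 0.0


def _zi_machinery(family: str, X: np.ndarray, W: np.ndarray, y: np.ndarray):
    """Closures over theta = [beta (count), b (inflate), (dispersion)]."""
    p, q = X.shape[1], W.shape[1]
    has_disp = family in ("negbin", "genpoisson")
    zero = y == 0

    def unpack(theta):
        return theta[:p], theta[p : p + q], (_unpack_disp(family, theta, p + q) if has_disp else 0.0)

    def pieces(theta):
        beta, b, disp = unpack(theta)
        xi = np.clip(X @ beta, -500, 500)
        eta = np.clip(W @ b, -500, 500)
        mu = np.exp(xi)
        if family == "genpoisson" and (disp >= 1.0 or np.any(mu * (1 - disp) + disp * y <= 0)):
            return None
        logp = -np.logaddexp(0.0, -eta)    # log pi
        log1mp = -np.logaddexp(0.0, eta)   # log (1 - pi)
        logf = fam.log_pmf_arr(family, y, mu, disp)
        logf0 = fam.log_zero_arr(family, mu, disp)
        ll = np.where(zero, np.logaddexp(logp, log1mp + logf0), log1mp + logf)
        return beta, b, disp, eta, mu, logp, log1mp, logf, logf0, ll

    def loglik_obs(theta):
        out = pieces(theta)
        if out is None:
            return np.full(len(y), -np.inf)
        return out[-1]

    def _grads(theta):
        out = pieces(theta)
        if out is None:
            return None
        beta, b, disp, eta, mu, logp, log1mp, logf, logf0, ll = out
        prob = expit(eta)
        f0 = np.exp(logf0)
        # zero subjects: S = pi + (1-pi) f0 = exp(ll)
        w_zero_count = np.exp(log1mp + logf0 - ll)      # weight on d log f0
        g_eta = np.where(zero, prob * (1 - prob) * (-np.expm1(logf0)) / np.exp(ll), -prob)
        d0 = fam.dlog_zero_dlogmu(family, mu, disp)
        dpos = fam.dlog_pmf_dlogmu(family, y, mu, disp)
        g_xi = np.where(zero, w_zero_count * d0, dpos)
        if has_disp:
            dd0 = fam.dlog_zero_ddisp(family, mu, disp)
            ddpos = fam.dlog_pmf_ddisp(family, y, mu, disp)
            g_disp = np.where(zero, w_zero_count * dd0, ddpos)
            if family == "negbin":
                g_disp = g_disp * disp  # chain to log(alpha)
        else:
            g_disp = None
        return ll, g_xi, g_eta, g_disp

    def negll_grad(theta):
        out = _grads(theta)
        if out is None or not np.all(np.isfinite(out[0])):
            return np.inf, np.zeros_like(theta)
        ll, g_xi, g_eta, g_disp = out
        grad = [X.T @ g_xi, W.T @ g_eta]
        if g_disp is not None:
            grad.append([np.sum(g_disp)])
        return -float(np.sum(ll)), -np.concatenate(grad)

    def score_obs(theta):
        out = _grads(theta)
        ll, g_xi, g_eta, g_disp = out
        cols = [g_xi[:, None] * X, g_eta[:, None] * W]
        if g_disp is not None:
            cols.append(g_disp[:, None])
        return np.hstack(cols)

    return unpack, negll_grad, loglik_obs, score_obs


def _zi_start(family: str, data: AnalysisDataset, p: int, q: int):
    y = data.outcome
    pois = fit_count_glm(data, "poisson")
    mu = np.exp(data.count_design.to_numpy() @ pois.count_coefficients)
    excess = float(np.mean(y == 0) - np.mean(np.exp(-mu)))
    pi0 = min(max(excess, 0.05), 0.95)
    b = np.zeros(q)
    b[0] = np.log(pi0 / (1 - pi0))
    # count part seeded from a Poisson fit restricted to the positive counts
    pos = np.where(y > 0)[0]
    try:
        beta = fit_count_glm(data.take(pos), "poisson").count_coefficients
    except Exception:
        beta = pois.count_coefficients
    theta = np.concatenate([beta, b])
    if family == "negbin":
        theta = np.concatenate([theta, [np.log(0.1)]])
    elif family == "genpoisson":
        theta = np.concatenate([theta, [0.05]])
    return theta


def fit_zero_inflated(data: AnalysisDataset, family: str = "poisson",
                      robust: bool = False) -> FittedModel:
    """Joint MLE of a zero-inflated count model (ZIP / ZINB / ZIGP).

    The count part uses ``data.count_design`` (log link; exponentiated
    coefficients are risk ratios for the number of detected polyps given no
    excess zero); the inflation part uses ``data.inflate_design`` (logit
    link on the odds of an excess zero; exponentiated coefficients are odds
    ratios).  ``robust=True`` gives the ZIRP analysis: identical point
    estimates with a sandwich covariance over the full parameter vector.

    Raises :class:`InstabilityError` when the inflation part diverges
    (|coefficient| > 15 on the logit scale) — the usual remedy is a hurdle
    model, whose zero part is an ordinary logistic fit.
    """
    if family not in ZI_KINDS:
        raise ValueError(f"family must be one of {tuple(ZI_KINDS)}")
    X = data.count_design.to_numpy(dtype=float)
    W = data.inflate_design.to_numpy(dtype=float)
    y = data.outcome.astype(float)
    p, q = X.shape[1], W.shape[1]

    if not (y == 0).any():
        return _zi_collapsed(data, family, robust, "no zeros in the outcome")

    unpack, negll_grad, loglik_obs, score_obs = _zi_machinery(family, X, W, y)
    theta0 = _zi_start(family, data, p, q)
    theta, converged = maximize_loglik(negll_grad, theta0, f"ZI {family}")
    bhat = theta[p : p + q]
    if np.max(np.abs(bhat)) > 15.0:
        # Distinguish the benign degenerate (pi -> 0: the mixture collapses
        # onto the plain count GLM) from genuine divergence.
        glm = fit_count_glm(data, family)
        if -negll_grad(theta)[0] <= glm.loglik + 1e-4:
            return _zi_collapsed(data, family, robust,
                                 "structural-zero probability driven to zero")
        raise InstabilityError(
            "inflation-part coefficients diverged (|b| > 15 on the logit scale); "
            "consider a hurdle model to avoid convergence issues"
        )
    if not converged:
        g = negll_grad(theta)[1]
        raise ConvergenceError(
            f"zero-inflated {family} fit did not converge; last |grad| = {np.max(np.abs(g)):.3g}"
        )

    names = list(data.count_design.columns) + [f"inflate:{c}" for c in data.inflate_design.columns]
    dispersion = None
    if family == "negbin":
        dispersion = float(np.exp(theta[-1]))
        names.append("log_alpha")
    elif family == "genpoisson":
        dispersion = float(theta[-1])
        names.append("delta")

    A = numerical_hessian(lambda v: negll_grad(v)[1], theta)
    vcov = np.linalg.pinv(A)
    kind = ZI_KINDS[family]
    model = FittedModel(
        kind=("ZIRP" if (robust and family == "poisson") else kind),
        family=family, params=theta, names=names, n_count=p, n_inflate=q,
        has_dispersion=family != "poisson", vcov=vcov, robust=False,
        loglik=float(np.sum(loglik_obs(theta))), loglik_obs=loglik_obs(theta),
        n_obs=len(y), converged=converged, dispersion=dispersion,
        score_obs_fn=score_obs, negll_grad_fn=negll_grad,
        fit_spec={"fitter": "zero_inflated", "family": family, "robust": robust},
    )
    if robust:
        model.vcov = sandwich_vcov(model)
        model.robust = True
    return model


def _zi_collapsed(data: AnalysisDataset, family: str, robust: bool,
                  reason: str) -> FittedModel:
    """Degenerate mixture with structural-zero probability 0: identical to
    the plain count GLM.  The inflation intercept is pinned far negative and
    its covariance entries set to zero."""
    warnings.warn(f"{reason}: zero-inflated fit collapses to the count GLM")
    glm = fit_count_glm(data, family, robust=robust)
    q = data.inflate_design.shape[1]
    p = glm.n_count
    b = np.full(q, 0.0)
    b[0] = -20.0
    if glm.has_dispersion:
        theta = np.concatenate([glm.params[:p], b, glm.params[p:]])
        names = glm.names[:p] + [f"inflate:{c}" for c in data.inflate_design.columns] + glm.names[p:]
    else:
        theta = np.concatenate([glm.params, b])
        names = list(glm.names) + [f"inflate:{c}" for c in data.inflate_design.columns]
    k = len(theta)
    vcov = np.zeros((k, k))
    idx = list(range(p)) + ([k - 1] if glm.has_dispersion else [])
    for a, ia in enumerate(idx):
        for bb, ib in enumerate(idx):
            vcov[ia, ib] = glm.vcov[a, bb]
    return FittedModel(
        kind=("ZIRP" if (robust and family == "poisson") else ZI_KINDS[family]),
        family=family, params=theta, names=names, n_count=p, n_inflate=q,
        has_dispersion=glm.has_dispersion, vcov=vcov, robust=glm.robust,
        loglik=glm.loglik, loglik_obs=glm.loglik_obs, n_obs=glm.n_obs,
        converged=glm.converged, dispersion=glm.dispersion,
        score_obs_fn=None, negll_grad_fn=None,
        fit_spec={"fitter": "zero_inflated", "family": family, "robust": robust},
    )


# ---------------------------------------------------------------------------
# hurdle models
# ---------------------------------------------------------------------------

def _truncated_machinery(family: str, X: np.ndarray, y: np.ndarray):
    """Zero-truncated count likelihood over positive counts."""
    p = X.shape[1]
    has_disp = family in ("negbin", "genpoisson")

    def unpack(theta):
        return theta[:p], (_unpack_disp(family, theta, p) if has_disp else 0.0)

    def core(theta):
        beta, disp = unpack(theta)
        mu = np.exp(np.clip(X @ beta, -500, 500))
        if family == "genpoisson" and (disp >= 1.0 or np.any(mu * (1 - disp) + disp * y <= 0)):
            return None
        logf0 = fam.log_zero_arr(family, mu, disp)
        ll = fam.log_pmf_arr(family, y, mu, disp) - np.log(-np.expm1(logf0))
        return beta, disp, mu, logf0, ll

    def loglik_obs(theta):
        out = core(theta)
        return np.full(len(y), -np.inf) if out is None else out[-1]

    def _grads(theta):
        out = core(theta)
        if out is None:
            return None
        beta, disp, mu, logf0, ll = out
        f0 = np.exp(logf0)
        ratio = f0 / (-np.expm1(logf0))
        g_xi = fam.dlog_pmf_dlogmu(family, y, mu, disp) + ratio * fam.dlog_zero_dlogmu(family, mu, disp)
        if has_disp:
            g_disp = fam.dlog_pmf_ddisp(family, y, mu, disp) + ratio * fam.dlog_zero_ddisp(family, mu, disp)
            if family == "negbin":
                g_disp = g_disp * disp
        else:
            g_disp = None
        return ll, g_xi, g_disp

    def negll_grad(theta):
        out = _grads(theta)
        if out is None or not np.all(np.isfinite(out[0])):
            return np.inf, np.zeros_like(theta)
        ll, g_xi, g_disp = out
        grad = [X.T @ g_xi]
        if g_disp is not None:
            grad.append([np.sum(g_disp)])
        return -float(np.sum(ll)), -np.concatenate(grad)

    def score_obs(theta):
        ll, g_xi, g_disp = _grads(theta)
        cols = [g_xi[:, None] * X]
        if g_disp is not None:
            cols.append(g_disp[:, None])
        return np.hstack(cols)

    return unpack, negll_grad, loglik_obs, score_obs


def fit_hurdle(data: AnalysisDataset, family: str = "poisson") -> FittedModel:
    """Hurdle model: logistic on any-polyp plus a zero-truncated count fit.

    The two likelihood factors are orthogonal, so the binary part is
    *identical* to an ordinary logistic regression (same coefficients, same
    odds ratios) and the total log-likelihood is the exact sum of the two
    parts.  The binary part models the odds of polyp *presence* (note the
    sign flip relative to the zero-inflated inflation part, which models
    excess-zero odds).
    """
    if family not in HURDLE_KINDS:
        raise ValueError(f"family must be one of {tuple(HURDLE_KINDS)}")
    y = data.outcome
    if not (y == 0).any():
        raise ValueError("hurdle binary part is degenerate: no zero counts")
    if not (y > 0).any():
        raise ValueError("hurdle count part is degenerate: no positive counts")

    logit = fit_logistic(data, design="inflate")

    pos = np.where(y > 0)[0]
    Xp = data.count_design.to_numpy(dtype=float)[pos]
    yp = y[pos].astype(float)
    unpack, negll_grad, loglik_obs, score_obs = _truncated_machinery(family, Xp, yp)
    beta0 = fit_count_glm(data.take(pos), "poisson").count_coefficients
    if family == "negbin":
        theta0 = np.concatenate([beta0, [np.log(0.1)]])
    elif family == "genpoisson":
        theta0 = np.concatenate([beta0, [0.05]])
    else:
        theta0 = beta0
    theta, converged = maximize_loglik(negll_grad, theta0, f"truncated {family}")
    if not converged:
        raise ConvergenceError(f"truncated {family} part did not converge")

    p = Xp.shape[1]
    q = logit.n_count
    names = list(data.count_design.columns)
    dispersion = None
    if family == "negbin":
        dispersion = float(np.exp(theta[-1]))
        disp_names = ["log_alpha"]
    elif family == "genpoisson":
        dispersion = float(theta[-1])
        disp_names = ["delta"]
    else:
        disp_names = []
    full_names = names + [f"zero:{c}" for c in data.inflate_design.columns] + disp_names
    full_params = np.concatenate([theta[:p], logit.params, theta[p:]])

    # block-diagonal covariance: truncated part and logistic part are orthogonal
    A = numerical_hessian(lambda v: negll_grad(v)[1], theta)
    Vt = np.linalg.pinv(A)
    k = len(full_params)
    vcov = np.zeros((k, k))
    t_idx = list(range(p)) + ([k - 1] if disp_names else [])
    for a, ia in enumerate(t_idx):
        for bb, ib in enumerate(t_idx):
            vcov[ia, ib] = Vt[a, bb]
    vcov[p : p + q, p : p + q] = logit.vcov

    # per-subject log-likelihood over the full sample
    ll_obs = logit.loglik_obs.copy()
    ll_obs[pos] += loglik_obs(theta)

    def full_score(params):
        beta_t = np.concatenate([params[:p], params[p + q :]])
        s = np.zeros((len(y), k))
        st = score_obs(beta_t)
        s[np.ix_(pos, t_idx)] = st
        s[:, p : p + q] = logit.score_obs_fn(params[p : p + q])
        return s

    return FittedModel(
        kind=HURDLE_KINDS[family], family=family, params=full_params,
        names=full_names, n_count=p, n_inflate=q,
        has_dispersion=bool(disp_names), vcov=vcov, robust=False,
        loglik=float(np.sum(ll_obs)), loglik_obs=ll_obs, n_obs=len(y),
        converged=converged and logit.converged, dispersion=dispersion,
        score_obs_fn=full_score, negll_grad_fn=None,
        fit_spec={"fitter": "hurdle", "family": family},
    )


# ---------------------------------------------------------------------------
# component predictions
# ---------------------------------------------------------------------------

def _check_design(model: FittedModel, data: AnalysisDataset) -> None:
    expect = model.count_names
    got = list(data.count_design.columns)
    if model.kind != "LR" and got != expect:
        raise ValueError(f"count design columns {got} do not match fitted model {expect}")


def predict_components(model: FittedModel, data: AnalysisDataset) -> MixturePrediction:
    """Per-subject predictions for any fitted model kind.

    For zero-inflated fits ``pi`` is the structural-zero probability; for
    hurdle fits it is re-interpreted as the total ``P(Y = 0)`` (all zeros
    come from the binary part); for single-distribution count fits it is 0;
    for logistic regression it is ``1 - fitted probability``.
    """
    _check_design(model, data)
    n = data.n_subjects
    disp = 0.0
    if model.has_dispersion:
        disp = model.dispersion if model.family != "negbin" else model.dispersion

    if model.kind == "LR":
        prob_pos = expit(data.count_design.to_numpy() @ model.count_coefficients)
        nan = np.full(n, np.nan)
        return MixturePrediction(pi=1 - prob_pos, mu=nan, prob_zero=1 - prob_pos,
                                 prob_pos=prob_pos, expected_count=nan,
                                 structural_posterior=np.ones(n))

    mu = np.exp(data.count_design.to_numpy() @ model.count_coefficients)
    f0 = np.exp(fam.log_zero_arr(model.family, mu, disp))

    if model.kind in ("PR", "RP", "NB", "GP"):
        return MixturePrediction(pi=np.zeros(n), mu=mu, prob_zero=f0,
                                 prob_pos=1 - f0, expected_count=mu,
                                 structural_posterior=np.zeros(n))

    W = data.inflate_design.to_numpy()
    eta = W @ model.inflate_coefficients
    if model.kind in ("ZHP", "ZHNB", "ZHGP"):
        prob_pos = expit(eta)            # binary part models presence
        prob_zero = 1 - prob_pos
        expected = prob_pos * mu / (1 - f0)
        return MixturePrediction(pi=prob_zero, mu=mu, prob_zero=prob_zero,
                                 prob_pos=prob_pos, expected_count=expected,
                                 structural_posterior=np.ones(n))

    pi = expit(eta)                      # inflation part models excess zeros
    prob_zero = pi + (1 - pi) * f0
    return MixturePrediction(pi=pi, mu=mu, prob_zero=prob_zero,
                             prob_pos=1 - prob_zero,
                             expected_count=(1 - pi) * mu,
                             structural_posterior=pi / prob_zero)
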