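"""Fitted-model container, Wald inference, and shared MLE machinery."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FittedModel", "ConvergenceError", "SeparationError", "InstabilityError",
           "maximize_loglik", "numerical_hessian"]

MODEL_KINDS = ("LR", "PR", "RP", "NB", "GP", "ZIP", "ZIRP", "ZINB", "ZIGP", "ZHP", "ZHNB")

GRAD_TOL = 1e-6          # converged when max |score| below this
OPT_GTOL = 1e-8          # optimizer target on the gradient norm
MAX_ITER = 500


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


class SeparationError(ConvergenceError):
    """Perfect separation in a logistic component."""


class InstabilityError(ConvergenceError):
    """Inflation-part coefficients diverged; a hurdle model is the usual fallback."""


@dataclass
class FittedModel:
    """Maximum-likelihood fit of any of the ten model families.

    ``params`` is the internal parameter vector: count coefficients, then
    inflation coefficients (if any), then dispersion (NB2 alpha is stored as
    ``log(alpha)``; GP delta is stored raw).  ``vcov`` lives in the same
    internal space.  Exponentiated count coefficients are risk ratios;
    exponentiated inflation coefficients are odds ratios.
    """

    kind: str
    family: str | None
    params: np.ndarray
    names: list[str]
    n_count: int                      # number of count-part coefficients
    n_inflate: int                    # number of inflation-part coefficients
    has_dispersion: bool
    vcov: np.ndarray
    robust: bool
    loglik: float
    loglik_obs: np.ndarray
    n_obs: int
    converged: bool
    dispersion: float | None = None
    score_obs_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    negll_grad_fn: Callable[[np.ndarray], tuple] | None = field(default=None, repr=False)
    fit_spec: dict = field(default_factory=dict, repr=False)

    # -- derived quantities ---------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    @property
    def count_coefficients(self) -> np.ndarray:
        return self.params[: self.n_count]

    @property
    def inflate_coefficients(self) -> np.ndarray:
        return self.params[self.n_count : self.n_count + self.n_inflate]

    @property
    def count_names(self) -> list[str]:
        return self.names[: self.n_count]

    @property
    def inflate_names(self) -> list[str]:
        return self.names[self.n_count : self.n_count + self.n_inflate]

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def coef_table(self, level: float = 0.95) -> pd.DataFrame:
        """Wald table: coefficient, SE, exp(coef) with CI, two-sided p.

        Count rows exponentiate to risk ratios; inflation rows to odds
        ratios. The dispersion row (if any) is reported untransformed on its
        natural scale without a ratio column.
        """
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se()
        rows = []
        for i, name in enumerate(self.names):
            part = ("count" if i < self.n_count
                    else "inflate" if i < self.n_count + self.n_inflate
                    else "dispersion")
            b, s = self.params[i], se[i]
            if part == "dispersion":
                rows.append((name, part, self.dispersion, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            zstat = b / s if s > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(zstat)) if s > 0 else np.nan
            rows.append((name, part, b, s, np.exp(b), np.exp(b - z * s), np.exp(b + z * s), p))
        return pd.DataFrame(
            rows, columns=["term", "part", "coef", "se", "ratio", "ci_low", "ci_high", "p"]
        )

    def group_effect(self, group_column: str, part: str = "count", level: float = 0.95):
        """(coef, ci_low, ci_high) on the log scale for the group term."""
        if part == "count":
            names, offset = self.count_names, 0
        else:
            names, offset = self.inflate_names, self.n_count
        # two-part fits prefix the zero-part names ("inflate:group", "zero:group")
        matches = [j for j, n in enumerate(names)
                   if n == group_column or n.split(":", 1)[-1] == group_column]
        if not matches:
            raise ValueError(f"model has no {part}-part term {group_column!r}")
        i = offset + matches[0]
        z = stats.norm.ppf(0.5 + level / 2.0)
        s = self.se()[i]
        b = self.params[i]
        return b, b - z * s, b + z * s


# ---------------------------------------------------------------------------
# optimization helpers
# ---------------------------------------------------------------------------

def numerical_hessian(grad_fn: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                      rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Hessian of a scalar function given its gradient."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def maximize_loglik(negll_grad: Callable, x0: np.ndarray, label: str = "model"):
    """Quasi-Newton maximization with a Nelder–Mead fallback.

    ``negll_grad(x)`` returns ``(-loglik, -score)``.  BFGS with analytic
    gradients is tried first (gradient-norm target 1e-8, max 500
    iterations); if the score has not vanished, Newton polishing with a
    ridge-regularized numerical Hessian follows, then Nelder–Mead as a last
    resort.  Returns ``(x_hat, converged)``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(negll_grad, x0, jac=True, method="BFGS",
                                options={"gtol": OPT_GTOL, "maxiter": MAX_ITER})
    x = res.x
    grad_fn = lambda v: negll_grad(v)[1]

    def gnorm(v):
        g = grad_fn(v)
        return np.max(np.abs(g)) if np.all(np.isfinite(g)) else np.inf

    if gnorm(x) > GRAD_TOL:
        x = _newton_polish(negll_grad, grad_fn, x)
    if gnorm(x) > GRAD_TOL:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nm = optimize.minimize(lambda v: negll_grad(v)[0], x, method="Nelder-Mead",
                                   options={"maxiter": 5000, "fatol": 1e-12, "xatol": 1e-10})
        cand = _newton_polish(negll_grad, grad_fn, nm.x)
        if negll_grad(cand)[0] <= negll_grad(x)[0]:
            x = cand
        warnings.warn(f"{label}: quasi-Newton stalled; used Nelder-Mead fallback")
    converged = gnorm(x) <= GRAD_TOL
    return x, converged


def _newton_polish(negll_grad, grad_fn, x, max_steps: int = 100):
    """Newton refinement with ridge-regularized numerical Hessians.

    Near a flat dispersion boundary the objective changes by less than one
    ulp per step, so a step is also accepted when it halves the gradient
    norm even if the objective is unchanged to machine precision.
    """
    x = np.asarray(x, dtype=float).copy()
    f_cur = negll_grad(x)[0]

    def gnorm(g):
        return np.max(np.abs(g)) if np.all(np.isfinite(g)) else np.inf

    g = grad_fn(x)
    for _ in range(max_steps):
        gn_cur = gnorm(g)
        if gn_cur <= OPT_GTOL:
            break
        H = numerical_hessian(grad_fn, x)
        ridge = 1e-10
        for _ in range(12):
            try:
                step = np.linalg.solve(H + ridge * np.eye(len(x)), g)
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        else:  # pragma: no cover
            break
        t, accepted = 1.0, False
        for _ in range(40):
            x_new = x - t * step
            f_new = negll_grad(x_new)[0]
            g_new = grad_fn(x_new)
            if np.isfinite(f_new) and (
                f_new < f_cur - 1e-12
                or (f_new <= f_cur + 1e-10 and gnorm(g_new) < 0.9 * gn_cur)
            ):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        x, f_cur, g = x_new, f_new, g_new
    return x
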