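"""Count-distribution families: Poisson, negative binomial (NB2), generalized Poisson.

All probability mass is evaluated in log space. Zero-heavy data make the
``pmf(0)`` terms dominate mixture likelihoods, and those terms underflow
quickly in natural space (e.g. Poisson ``pmf(0) = e^{-mu}`` at ``mu = 50``),
so every routine here returns log-probabilities and mixtures are combined
with log-sum-exp downstream.

Parameterizations
-----------------
* **Poisson**: mean ``mu``, variance ``mu``.
* **Negative binomial (NB2)**: mean ``mu``, dispersion ``alpha >= 0``,
  variance ``mu + alpha * mu**2``.  As ``alpha -> 0`` the NB2 pmf converges
  pointwise to the Poisson pmf with the same mean.
* **Generalized Poisson** (restricted, Consul–Famoye GP-1): mean ``mu``,
  dispersion ``delta`` with ``max(-1, -mu/4) < delta < 1``; variance
  ``mu / (1 - delta)**2``.  ``delta = 0`` recovers the Poisson; ``delta < 0``
  gives underdispersion (with the usual finite-support truncation of the
  restricted GP), ``delta > 0`` overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, psi

__all__ = [
    "CountFamily",
    "FAMILY_NAMES",
    "log_pmf",
    "zero_prob",
    "log_pmf_truncated",
]

FAMILY_NAMES = ("poisson", "negbin", "genpoisson")

_NEGINF = -np.inf


@dataclass(frozen=True)
class CountFamily:
    """A count distribution with a mean and (optionally) a dispersion.

    Parameters
    ----------
    name : {"poisson", "negbin", "genpoisson"}
    mu : float
        Positive mean.
    alpha : float
        NB2 dispersion (ignored unless ``name == "negbin"``); must be >= 0.
    delta : float
        Generalized-Poisson dispersion (ignored unless ``name ==
        "genpoisson"``); must lie in ``(max(-1, -mu/4), 1)``.
    """

    name: str
    mu: float
    alpha: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in FAMILY_NAMES:
            raise ValueError(f"unknown family {self.name!r}; choose from {FAMILY_NAMES}")
        if not (self.mu >= 0):
            raise ValueError("mu must be non-negative")
        if self.name == "negbin" and self.alpha < 0:
            raise ValueError("NB2 dispersion alpha must be non-negative")
        if self.name == "genpoisson":
            lo = max(-1.0, -self.mu / 4.0)
            if not (lo < self.delta < 1.0):
                raise ValueError(
                    f"genpoisson delta={self.delta} outside admissible range "
                    f"({lo}, 1) for mu={self.mu}"
                )


# ---------------------------------------------------------------------------
# array kernels (used by the regression modules; `y`, `mu` may be arrays)
# ---------------------------------------------------------------------------

def _log_pmf_poisson(y, mu):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mu > 0, y * np.log(np.where(mu > 0, mu, 1.0)) - mu, np.where(y == 0, 0.0, _NEGINF))
    return out - gammaln(y + 1.0)


def _log_pmf_negbin(y, mu, alpha):
    """NB2 log-pmf via the gamma-function form.

    log f(y) = ln Γ(y + r) − ln Γ(r) − ln Γ(y+1)
             + r·ln(r / (r + mu)) + y·ln(mu / (r + mu)),   r = 1/alpha.
    """
    if np.all(alpha == 0):
        return _log_pmf_poisson(y, mu)
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = 1.0 / alpha
    denom = r + mu
    with np.errstate(divide="ignore"):
        logmu = np.where(mu > 0, np.log(np.where(mu > 0, mu, 1.0)), _NEGINF)
        ymax = int(np.max(y)) if y.size else 0
        if alpha < 1e-2 and ymax <= 10_000:
            # near the Poisson limit the gammaln differences of huge
            # arguments lose ~ulp(r log r) per subject; rewrite
            #   lnG(y+r) - lnG(r) - y ln(r+mu) = sum_{j<y} log1p((j-mu)/(r+mu))
            # and r ln(r/(r+mu)) = -r log1p(mu/r), both exact small terms.
            js = np.arange(ymax, dtype=float)
            b = np.broadcast(y, mu)
            yb = np.broadcast_to(y, b.shape)[..., None]
            mb = np.broadcast_to(mu, b.shape)[..., None]
            terms = np.where(yb > js, np.log1p((js - mb) / (r + mb)), 0.0)
            out = (
                terms.sum(axis=-1)
                - r * np.log1p(mu / r)
                + y * logmu
                - gammaln(y + 1.0)
            )
        else:
            out = (
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1.0)
                - r * np.log1p(mu / r)
                + y * (logmu - np.log(denom))
            )
    return np.where((y == 0) & (mu == 0), 0.0, out)


def _log_pmf_genpoisson(y, mu, delta):
    """Restricted GP-1 log-pmf, mean-parameterized: theta = mu (1 - delta).

    log f(y) = ln theta + (y-1)·ln(theta + delta y) − ln Γ(y+1) − theta − delta y.
    Terms with ``theta + delta*y <= 0`` (beyond the truncation point when
    ``delta < 0``) get probability zero.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = mu * (1.0 - delta)
    lam = theta + delta * y
    valid = (lam > 0) & (theta > 0)
    lam_safe = np.where(valid, lam, 1.0)
    theta_safe = np.where(theta > 0, theta, 1.0)
    out = (
        np.log(theta_safe)
        + (y - 1.0) * np.log(lam_safe)
        - gammaln(y + 1.0)
        - theta
        - delta * y
    )
    out = np.where(valid, out, _NEGINF)
    return np.where((y == 0) & (mu == 0), 0.0, out)


def log_pmf_arr(name: str, y, mu, disp: float = 0.0):
    """Vectorized log-pmf for a named family (dispersion scalar)."""
    if name == "poisson":
        return _log_pmf_poisson(y, mu)
    if name == "negbin":
        return _log_pmf_negbin(y, mu, disp)
    if name == "genpoisson":
        return _log_pmf_genpoisson(y, mu, disp)
    raise ValueError(f"unknown family {name!r}")


def log_zero_arr(name: str, mu, disp: float = 0.0):
    """Vectorized ``log P(Y = 0)``, in closed form for each family."""
    mu = np.asarray(mu, dtype=float)
    if name == "poisson":
        return -mu
    if name == "negbin":
        if disp == 0:
            return -mu
        return -np.log1p(disp * mu) / disp
    if name == "genpoisson":
        return -mu * (1.0 - disp)
    raise ValueError(f"unknown family {name!r}")


# derivatives used by the likelihood modules ---------------------------------

def dlog_pmf_dlogmu(name: str, y, mu, disp: float = 0.0):
    """d log f(y) / d log(mu) — chain-ruled for a log-link mean."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if name == "poisson":
        return y - mu
    if name == "negbin":
        return (y - mu) / (1.0 + disp * mu)
    if name == "genpoisson":
        theta = mu * (1.0 - disp)
        lam = theta + disp * y
        dtheta = 1.0 / theta + (y - 1.0) / lam - 1.0
        return dtheta * (1.0 - disp) * mu
    raise ValueError(name)


def dlog_zero_dlogmu(name: str, mu, disp: float = 0.0):
    mu = np.asarray(mu, dtype=float)
    if name == "poisson":
        return -mu
    if name == "negbin":
        return -mu / (1.0 + disp * mu)
    if name == "genpoisson":
        return -mu * (1.0 - disp)
    raise ValueError(name)


def dlog_pmf_ddisp(name: str, y, mu, disp: float):
    """d log f(y) / d dispersion (alpha for NB2, delta for GP)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if name == "negbin":
        r = 1.0 / disp
        denom = r + mu
        ymax = int(np.max(y)) if y.size else 0
        if disp < 1e-2 and ymax <= 10_000:
            # psi(y+r) - psi(r) computed as the exact finite sum
            # sum_{j<y} 1/(r+j), and log(r/(r+mu)) via log1p: the naive
            # forms cancel catastrophically once amplified by r^2.
            js = np.arange(ymax, dtype=float)
            hsum = ((y[..., None] > js) / (r + js)).sum(axis=-1)
            dldr = hsum + np.log1p(-mu / denom) + (mu - y) / denom
        else:
            dldr = psi(y + r) - psi(r) + np.log(r) - np.log(denom) + (mu - y) / denom
        return -dldr * r * r  # dr/dalpha = -1/alpha^2
    if name == "genpoisson":
        theta = mu * (1.0 - disp)
        lam = theta + disp * y
        dtheta = 1.0 / theta + (y - 1.0) / lam - 1.0
        return dtheta * (-mu) + (y - 1.0) * y / lam - y
    raise ValueError(name)


def dlog_zero_ddisp(name: str, mu, disp: float):
    mu = np.asarray(mu, dtype=float)
    if name == "negbin":
        am = disp * mu
        if np.all(am < 1e-3):
            # series of d/dalpha [-log1p(alpha mu)/alpha]; the closed form
            # is a difference of two O(mu/alpha) terms that cancels badly
            return mu**2 / 2.0 - 2.0 * disp * mu**3 / 3.0
        return np.log1p(am) / disp**2 - mu / (disp * (1.0 + am))
    if name == "genpoisson":
        return mu
    raise ValueError(name)


# ---------------------------------------------------------------------------
# scalar public API
# ---------------------------------------------------------------------------

def _disp(family: CountFamily) -> float:
    return family.alpha if family.name == "negbin" else family.delta


def log_pmf(family: CountFamily, y: int) -> float:
    """Log-probability of observing count ``y`` under ``family``.

    Raises ``ValueError`` for negative or non-integer ``y``.
    """
    if y < 0 or int(y) != y:
        raise ValueError(f"y must be a non-negative integer, got {y}")
    return float(log_pmf_arr(family.name, y, family.mu, _disp(family)))


def zero_prob(family: CountFamily) -> float:
    """``P(Y = 0)`` under ``family`` (closed form; equals ``exp(log_pmf(., 0))``)."""
    return float(np.exp(log_zero_arr(family.name, family.mu, _disp(family))))


def log_pmf_truncated(family: CountFamily, y: int) -> float:
    """Log-pmf of the zero-truncated distribution: ``log[f(y) / (1 - f(0))]``.

    Requires ``y >= 1`` and ``P(Y=0) < 1``.
    """
    if y < 1 or int(y) != y:
        raise ValueError(f"truncated pmf defined for positive integers, got y={y}")
    p0 = zero_prob(family)
    if p0 >= 1.0:
        raise ValueError("distribution is degenerate at zero; truncation undefined")
    return log_pmf(family, y) - np.log1p(-p0)
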