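"""Excess-zero and dispersion diagnostics, goodness of fit, model selection.

The battery mirrors how a careful count-data analysis proceeds:

1. *Are there excess zeros?* — a score test against the fitted Poisson
   (van den Broek form) and a bias-corrected Vuong comparison of the
   zero-inflated fit against the plain one.
2. *What kind of zeros?* — structural (truly no polyps) vs mixed with
   sampling zeros (polyps missed at colonoscopy).  This is a substantive
   judgment about the data-generating process, supplied by the analyst,
   not inferred from data.
3. *Is there residual dispersion once excess zeros are removed?* — an
   auxiliary-regression overdispersion test and the NB2 boundary
   likelihood-ratio test, run on a reduced dataset from which the
   predicted number of structural zeros has been deterministically removed.
4. *Which model fits?* — AIC/BIC/log-likelihood plus a chi-square
   goodness-of-fit test on observed vs expected count categories
   (counts topcoded into a final ``6+`` cell by default).

``select_model_flowchart`` walks these branches and records the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import families as fam
from .api import fit_model
from .data import AnalysisDataset
from .glm import fit_count_glm
from .mixture import fit_zero_inflated, predict_components
from .model import FittedModel

__all__ = [
    "TestResult", "SelectionReport",
    "score_test_zero_inflation", "vuong_test_corrected",
    "remove_excess_zeros", "dispersion_tests",
    "gof_chisq", "information_criteria", "select_model_flowchart",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: int | None = None
    direction: str | None = None

    def __str__(self) -> str:
        df = f", df={self.df}" if self.df is not None else ""
        note = f" [{self.direction}]" if self.direction else ""
        return f"{self.test_name}: stat={self.statistic:.4g}{df}, p={self.p_value:.4g}{note}"


# ---------------------------------------------------------------------------
# excess-zero tests
# ---------------------------------------------------------------------------

def score_test_zero_inflation(poisson_fit: FittedModel, data: AnalysisDataset) -> TestResult:
    """Score test for zero inflation against a fitted Poisson regression.

    With ``p0_i = exp(-mu_i)`` from the Poisson fit,

        S = [sum_i (1{y_i=0} - p0_i)/p0_i]^2 /
            [sum_i (1 - p0_i)/p0_i - n*ybar]

    referred to chi-square(1).  A significant result indicates more zeros
    than the Poisson mean structure can explain.
    """
    if poisson_fit.family != "poisson" or poisson_fit.n_inflate:
        raise ValueError("score test requires a plain Poisson regression fit")
    y = data.outcome
    mu = np.exp(data.count_design.to_numpy() @ poisson_fit.count_coefficients)
    p0 = np.exp(-mu)
    num = np.sum(((y == 0) - p0) / p0)
    denom = np.sum((1 - p0) / p0) - len(y) * y.mean()
    if denom <= 0:
        warnings.warn("score-test denominator non-positive (underdispersion); not applicable")
        return TestResult("score_zero_inflation", np.nan, np.nan, df=1,
                          direction="not applicable (underdispersion)")
    stat = num**2 / denom
    return TestResult("score_zero_inflation", float(stat),
                      float(stats.chi2.sf(stat, 1)), df=1)


def vuong_test_corrected(model_zi: FittedModel, model_plain: FittedModel,
                         correction: str = "AIC") -> TestResult:
    """Bias-corrected Vuong test for a zero-inflated vs a plain count model.

    Uses per-subject log-likelihood differences ``m_i``; the AIC (BIC)
    correction subtracts the parameter-count penalty difference spread over
    subjects.  Positive Z favors the inflated model; the p-value is
    one-sided for its superiority.
    """
    if model_zi.n_obs != model_plain.n_obs:
        raise ValueError("models were fit to different numbers of subjects")
    n = model_zi.n_obs
    m = model_zi.loglik_obs - model_plain.loglik_obs
    dk = model_zi.n_params - model_plain.n_params
    if correction == "AIC":
        m = m - dk / n
    elif correction == "BIC":
        m = m - dk * np.log(n) / (2.0 * n)
    elif correction != "none":
        raise ValueError("correction must be one of 'none', 'AIC', 'BIC'")
    s = m.std(ddof=1)
    if s < 1e-12:
        return TestResult("vuong_corrected", 0.0, 1.0,
                          direction="degenerate: identical per-subject likelihoods")
    z = np.sqrt(n) * m.mean() / s
    return TestResult("vuong_corrected", float(z), float(stats.norm.sf(z)),
                      direction=f"{correction} correction; positive favors inflated")


# ---------------------------------------------------------------------------
# excess-zero removal and dispersion
# ---------------------------------------------------------------------------

def remove_excess_zeros(data: AnalysisDataset, zi_fit: FittedModel) -> AnalysisDataset:
    """Remove the predicted number of structural zeros from the data.

    ``m = round(sum_i pi_hat_i)`` zero-count records are dropped, chosen as
    the observed zeros with the highest posterior probability of being
    structural (ties broken by record order).  Deterministic by design so
    the downstream dispersion tests are reproducible.
    """
    pred = predict_components(zi_fit, data)
    m = int(np.round(np.sum(pred.pi)))
    zeros = np.where(data.outcome == 0)[0]
    if m == 0:
        return data
    if m > len(zeros):
        warnings.warn(f"predicted structural zeros ({m}) exceed observed zeros "
                      f"({len(zeros)}); capping")
        m = len(zeros)
    post = pred.structural_posterior[zeros]
    order = np.lexsort((zeros, -post))      # highest posterior first, stable
    drop = set(zeros[order[:m]].tolist())
    keep = np.array([i for i in range(data.n_subjects) if i not in drop])
    return data.take(keep)


def dispersion_tests(data: AnalysisDataset) -> tuple[TestResult, TestResult]:
    """Overdispersion tests on (possibly excess-zero-reduced) count data.

    (a) Auxiliary regression: with ``mu_hat`` from a Poisson fit, regress
    ``((y - mu)^2 - y)/mu`` on ``mu`` without intercept; the slope's t-test
    is two-sided, slope sign gives the direction.
    (b) NB2 boundary likelihood-ratio test: ``2(LL_NB - LL_PR)`` referred
    to the 50:50 mixture of a point mass at 0 and chi-square(1); reports
    the estimated alpha.
    """
    pois = fit_count_glm(data, "poisson")
    y = data.outcome.astype(float)
    mu = np.exp(data.count_design.to_numpy() @ pois.count_coefficients)
    zres = ((y - mu) ** 2 - y) / mu
    slope = float(np.sum(zres * mu) / np.sum(mu * mu))
    resid = zres - slope * mu
    n = len(y)
    se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(mu * mu)))
    t = slope / se
    direction = "over" if slope > 0 else "under"
    mean_var = f"mean={y.mean():.2f}, var={y.var(ddof=1):.2f}"
    aux = TestResult("auxiliary_overdispersion", float(t),
                     float(2 * stats.t.sf(abs(t), n - 1)), df=n - 1,
                     direction=f"{direction}dispersion; {mean_var}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb = fit_count_glm(data, "negbin")
    lr = max(2.0 * (nb.loglik - pois.loglik), 0.0)
    p_boundary = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 1.0
    boundary = TestResult("nb_boundary_lr", float(lr), float(p_boundary), df=1,
                          direction=f"alpha_hat={nb.dispersion:.4g}")
    return aux, boundary


# ---------------------------------------------------------------------------
# goodness of fit and information criteria
# ---------------------------------------------------------------------------

def _cell_probabilities(model: FittedModel, data: AnalysisDataset, max_cell: int) -> np.ndarray:
    """(n_subjects, max_cell+1) matrix of P(Y in cell c); last cell is `max_cell+`."""
    if model.kind == "LR":
        raise ValueError("goodness-of-fit on count categories is undefined for LR")
    pred = predict_components(model, data)
    mu = pred.mu
    disp = model.dispersion if model.has_dispersion else 0.0
    ys = np.arange(max_cell)
    logf = np.stack([fam.log_pmf_arr(model.family, np.full_like(mu, yv), mu, disp)
                     for yv in ys], axis=1)
    f = np.exp(logf)
    if model.kind in ("ZHP", "ZHNB", "ZHGP"):
        f0 = np.exp(fam.log_zero_arr(model.family, mu, disp))
        P = pred.prob_pos[:, None] * f / (1 - f0)[:, None]
        P[:, 0] = pred.prob_zero
    elif model.n_inflate:
        P = (1 - pred.pi)[:, None] * f
        P[:, 0] = pred.prob_zero
    else:
        P = f
    tail = np.clip(1.0 - P.sum(axis=1), 0.0, 1.0)
    return np.hstack([P, tail[:, None]])


def gof_chisq(model: FittedModel, data: AnalysisDataset, max_cell: int = 6,
              df_adjust: int = 2) -> TestResult:
    """Chi-square goodness of fit on observed vs expected count categories.

    Cells are ``0, 1, ..., max_cell-1`` and ``max_cell+``; expected counts
    come from summing per-subject model probabilities.  Cells with expected
    count below 1 are merged upward.  ``df = cells - 1 - df_adjust``; the
    adjustment (default 2) accounts for estimated parameters and is always
    reported alongside the statistic.  A non-significant p indicates a good
    fit.
    """
    P = _cell_probabilities(model, data, max_cell)
    expected = P.sum(axis=0)
    observed = np.array([np.sum(np.minimum(data.outcome, max_cell) == c)
                         for c in range(max_cell + 1)], dtype=float)
    # merge sparse cells upward into their right neighbor (tail absorbs)
    O, E = list(observed), list(expected)
    i = 0
    merged = False
    while i < len(E) - 1:
        if E[i] < 1.0:
            E[i + 1] += E[i]
            O[i + 1] += O[i]
            del E[i], O[i]
            merged = True
        else:
            i += 1
    if len(E) > 1 and E[-1] < 1.0:
        E[-2] += E[-1]
        O[-2] += O[-1]
        del E[-1], O[-1]
        merged = True
    O, E = np.array(O), np.array(E)
    stat = float(np.sum((O - E) ** 2 / E))
    dfree = max(len(E) - 1 - df_adjust, 1)
    note = f"cells={len(E)}, df_adjust={df_adjust}" + ("; sparse cells merged" if merged else "")
    return TestResult("gof_chisq", stat, float(stats.chi2.sf(stat, dfree)),
                      df=dfree, direction=note)


def information_criteria(model: FittedModel) -> dict:
    """AIC, BIC and log-likelihood (BIC is the primary ranking criterion)."""
    return {"AIC": model.aic, "BIC": model.bic, "LL": model.loglik}


# ---------------------------------------------------------------------------
# flowchart
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    excess_zero_tests: tuple[TestResult, TestResult]
    zero_type: str | None
    dispersion_after_removal: tuple[TestResult, TestResult] | None
    fit_table: pd.DataFrame
    recommended_model: str
    rationale: list[str] = field(default_factory=list)


_INFLATED_CANDIDATES = ["ZIP", "ZIRP", "ZINB", "ZIGP"]
_HURDLE_CANDIDATES = ["ZHP", "ZHNB"]
_SINGLE_CANDIDATES = ["PR", "RP", "NB", "GP"]


def _fit_table(data: AnalysisDataset, kinds: list[str], max_cell: int) -> pd.DataFrame:
    rows = []
    for kind in kinds:
        try:
            m = fit_model(kind, data)
            gof = gof_chisq(m, data, max_cell=max_cell)
            rows.append((kind, m.aic, m.bic, m.loglik, gof.statistic, gof.p_value))
        except Exception as err:  # non-convergence of one candidate is informative, not fatal
            rows.append((kind, np.nan, np.nan, np.nan, np.nan, np.nan))
            warnings.warn(f"{kind} fit failed during selection: {err}")
    return pd.DataFrame(rows, columns=["model", "AIC", "BIC", "LL", "GOF", "GOF_p"])


def select_model_flowchart(data: AnalysisDataset, zero_type: str | None = None,
                           fit_all: bool = True, alpha_level: float = 0.05,
                           max_cell: int = 6) -> SelectionReport:
    """Walk the model-selection flowchart and return a reasoned recommendation.

    Branches: (1) excess zeros present (score + Vuong)?  If not, pick a
    single-distribution family from the dispersion tests.  (2) If present,
    the declared ``zero_type`` ("structural" -> hurdle family, "mixed" ->
    inflated family) picks the branch.  (3) Within the branch the
    post-removal dispersion decides Poisson-with-robust-variance vs NB.
    (4) BIC and goodness of fit break remaining ties when ``fit_all``.
    """
    rationale: list[str] = []
    has_zeros = (data.outcome == 0).any()
    if zero_type is not None:
        if zero_type not in ("structural", "mixed"):
            raise ValueError("zero_type must be 'structural' or 'mixed'")
        if not has_zeros:
            raise ValueError("zero_type declared but the outcome contains no zeros")

    pois = fit_count_glm(data, "poisson")
    if has_zeros:
        zip_fit = fit_zero_inflated(data, "poisson")
        score = score_test_zero_inflation(pois, data)
        vuong = vuong_test_corrected(zip_fit, pois, correction="AIC")
    else:
        zip_fit = None
        score = TestResult("score_zero_inflation", 0.0, 1.0, df=1, direction="no zeros")
        vuong = TestResult("vuong_corrected", 0.0, 1.0, direction="no zeros")
    excess = (np.nan_to_num(score.p_value, nan=1.0) < alpha_level
              and vuong.p_value < alpha_level)
    rationale.append(
        f"excess zeros: score p={score.p_value:.3g}, Vuong p={vuong.p_value:.3g} -> "
        + ("present" if excess else "absent")
    )

    if not excess:
        aux, boundary = dispersion_tests(data)
        over = aux.p_value < alpha_level and aux.statistic > 0
        under = aux.p_value < alpha_level and aux.statistic < 0
        if over and boundary.p_value < alpha_level:
            recommended = "NB"
            rationale.append(f"overdispersion (aux p={aux.p_value:.3g}) -> NB")
        elif under:
            recommended = "RP"
            rationale.append(f"underdispersion (aux p={aux.p_value:.3g}) -> GP or "
                             "Poisson with robust variance; robust Poisson recommended")
        else:
            recommended = "PR"
            rationale.append("equidispersion -> Poisson (robust variance optional)")
        candidates = _SINGLE_CANDIDATES if fit_all else [recommended]
        table = _fit_table(data, candidates, max_cell)
        return SelectionReport((score, vuong), zero_type, (aux, boundary),
                               table, recommended, rationale)

    if zero_type is None:
        raise ValueError(
            "excess zeros detected: declare zero_type='structural' (all zeros are "
            "true absences -> hurdle) or 'mixed' (sampling zeros possible -> inflated)"
        )

    reduced = remove_excess_zeros(data, zip_fit)
    aux, boundary = dispersion_tests(reduced)
    over = aux.p_value < alpha_level and aux.statistic > 0 and boundary.p_value < alpha_level
    rationale.append(
        f"dispersion after removing excess zeros: aux p={aux.p_value:.3g}, "
        f"NB-boundary p={boundary.p_value:.3g} -> {'over' if over else 'equi/under'}dispersed"
    )

    if zero_type == "structural":
        recommended = "ZHNB" if over else "ZHP"
        rationale.append(f"structural zeros only -> hurdle family ({recommended})")
        candidates = _HURDLE_CANDIDATES
    else:
        recommended = "ZINB" if over else "ZIRP"
        rationale.append(
            f"mixed zeros -> inflated family ({recommended}"
            + ("" if over else "; robust variance covers residual misspecification") + ")"
        )
        candidates = _INFLATED_CANDIDATES

    if fit_all:
        table = _fit_table(data, candidates + (_HURDLE_CANDIDATES if zero_type == "mixed" else []),
                           max_cell)
        ok = table.dropna(subset=["BIC"])
        if len(ok):
            best_bic = ok.loc[ok["BIC"].idxmin(), "model"]
            good_fit = ok[ok["GOF_p"] >= alpha_level]["model"].tolist()
            rationale.append(f"BIC favors {best_bic}; adequate GOF: {good_fit or 'none'}")
            # ZIP and ZIRP (or ZHP) share point estimates; prefer the branch pick
            # unless BIC strictly contradicts it within the same family class.
            if recommended not in ok["model"].values:
                recommended = best_bic
    else:
        table = _fit_table(data, [recommended], max_cell)
    return SelectionReport((score, vuong), zero_type, (aux, boundary),
                           table, recommended, rationale)
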