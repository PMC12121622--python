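"""Single-distribution regressions: closed-form identities, statsmodels
cross-checks, sandwich-variance behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from zicount import fit_count_glm, fit_logistic, sandwich_vcov
from zicount.data import AnalysisDataset
from zicount.model import SeparationError

from conftest import make_dataset


def two_by_two(n11, n10, n01, n00):
    """Dataset for a 2x2 table: group 1 has n11 positives / n10 zeros."""
    y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]).astype(int)
    g = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    return make_dataset(y, g)


class TestLogistic:
    def test_closed_form_2x2_odds_ratio(self):
        # margins from a randomized trial arm comparison: 87/211 vs 92/214
        data = two_by_two(87, 124, 92, 122)
        m = fit_logistic(data)
        hand = (87 * 122) / (92 * 124)
        b = m.params[m.names.index("group")]
        assert np.exp(b) == pytest.approx(hand, rel=1e-8)

    def test_balanced_rates_give_unit_or(self):
        data = two_by_two(40, 60, 40, 60)
        m = fit_logistic(data)
        assert np.exp(m.params[m.names.index("group")]) == pytest.approx(1.0, abs=1e-8)

    def test_matches_statsmodels(self, small_counts):
        m = fit_logistic(small_counts)
        sm_fit = sm.Logit((small_counts.outcome > 0).astype(float),
                          small_counts.count_design.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(m.params, np.asarray(sm_fit.params), atol=1e-6)
        np.testing.assert_allclose(m.se(), np.asarray(sm_fit.bse), rtol=1e-4)

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 0])
        g = (y > 0).astype(float)
        with pytest.raises(SeparationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_logistic(make_dataset(y, g))


class TestCountGLM:
    def test_intercept_only_poisson_mean_identity(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(2.3, 300)
        y[0] = max(y[0], 1)
        const = pd.DataFrame({"const": np.ones(300)})
        data = AnalysisDataset(outcome=y, count_design=const,
                               inflate_design=const.copy(), group_column="group")
        m = fit_count_glm(data, "poisson")
        assert np.exp(m.params[0]) == pytest.approx(y.mean(), rel=1e-8)

    @pytest.mark.parametrize("family", ["poisson", "negbin"])
    def test_matches_statsmodels(self, small_counts, family):
        m = fit_count_glm(small_counts, family)
        X = small_counts.count_design.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "poisson":
                ref = sm.Poisson(small_counts.outcome, X).fit(disp=0)
                np.testing.assert_allclose(m.params, np.asarray(ref.params), atol=1e-6)
            else:
                ref = sm.NegativeBinomial(small_counts.outcome, X).fit(disp=0)
                np.testing.assert_allclose(m.count_coefficients,
                                           np.asarray(ref.params)[:-1], atol=1e-5)
                assert m.dispersion == pytest.approx(np.asarray(ref.params)[-1], rel=1e-3)
        assert m.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_poisson(self):
        rng = np.random.default_rng(11)
        n = 5000
        g = rng.binomial(1, 0.5, n)
        y = rng.poisson(np.exp(0.1 + 0.4 * g))
        m = fit_count_glm(make_dataset(y, g), "poisson")
        b = m.params[m.names.index("group")]
        se = m.se()[m.names.index("group")]
        assert abs(b - 0.4) < 3 * se

    def test_score_vanishes_at_optimum(self, small_counts):
        for family in ["poisson", "negbin", "genpoisson"]:
            m = fit_count_glm(small_counts, family)
            _, g = m.negll_grad_fn(m.params)
            assert np.max(np.abs(g)) < 1e-6

    def test_genpoisson_underdispersion_admissible(self):
        rng = np.random.default_rng(5)
        # binomial counts are underdispersed: GP should pick delta < 0
        y = rng.binomial(8, 0.4, 400)
        y[y == 0] = 0
        m = fit_count_glm(make_dataset(y, rng.binomial(1, 0.5, 400)), "genpoisson")
        assert m.dispersion < 0


class TestSandwich:
    def test_duplication_halves_vcov(self, small_counts):
        m1 = fit_count_glm(small_counts, "poisson")
        V1 = sandwich_vcov(m1)
        doubled = small_counts.take(np.tile(np.arange(small_counts.n_subjects), 2))
        m2 = fit_count_glm(doubled, "poisson")
        V2 = sandwich_vcov(m2)
        np.testing.assert_allclose(V2, V1 / 2, rtol=1e-6)

    def test_robust_close_to_model_based_under_equidispersion(self):
        rng = np.random.default_rng(21)
        n = 5000
        g = rng.binomial(1, 0.5, n)
        y = rng.poisson(np.exp(0.3 + 0.3 * g))
        m = fit_count_glm(make_dataset(y, g), "poisson")
        robust = np.sqrt(np.diag(sandwich_vcov(m)))
        model_se = m.se()
        np.testing.assert_allclose(robust, model_se, rtol=0.10)

    def test_robust_exceeds_model_se_under_overdispersion(self):
        rng = np.random.default_rng(22)
        n = 2000
        g = rng.binomial(1, 0.5, n)
        mu = np.exp(0.3 + 0.3 * g)
        lam = rng.gamma(1.0, mu)          # NB with alpha = 1
        y = rng.poisson(lam)
        m = fit_count_glm(make_dataset(y, g), "poisson")
        robust_se = np.sqrt(np.diag(sandwich_vcov(m)))
        j = m.names.index("group")
        assert robust_se[j] > m.se()[j]

    def test_matches_statsmodels_hc0(self, small_counts):
        m = fit_count_glm(small_counts, "poisson", robust=True)
        X = small_counts.count_design.to_numpy()
        ref = sm.Poisson(small_counts.outcome, X).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(np.sqrt(np.diag(m.vcov)), np.asarray(ref.bse), rtol=1e-4)
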