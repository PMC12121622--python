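"""Zero-inflated and hurdle fits: likelihood identities, degenerate cases,
statsmodels cross-check, parameter recovery."""

import warnings

import numpy as np
import pytest
from scipy.special import expit, logsumexp
from statsmodels.discrete.count_model import (ZeroInflatedNegativeBinomialP,
                                              ZeroInflatedPoisson)

from zicount import (Scenario, fit_count_glm, fit_hurdle, fit_logistic,
                     fit_zero_inflated, generate_dataset, predict_components)
from zicount.families import log_pmf_arr, log_zero_arr
from zicount.mixture import _zi_machinery

from conftest import make_dataset


@pytest.fixture(scope="module")
def zi_fit(zi_dataset):
    data, _, _ = zi_dataset
    return fit_zero_inflated(data, "poisson"), data


class TestZeroInflated:
    def test_matches_statsmodels_zip(self, zi_fit):
        m, data = zi_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = ZeroInflatedPoisson(
                data.outcome, data.count_design.to_numpy(),
                exog_infl=data.inflate_design.to_numpy(), inflation="logit",
            ).fit(disp=0)
        mine = np.concatenate([m.inflate_coefficients, m.count_coefficients])
        assert m.loglik >= ref.llf - 1e-6
        np.testing.assert_allclose(mine, np.asarray(ref.params), atol=5e-4)

    def test_matches_statsmodels_zinb(self, zi_dataset):
        scn = Scenario(n_subjects=600, structural_zero_prob=0.4,
                       sampling_zero_target=0.25, count_family="negbin", alpha=0.5)
        data, _ = generate_dataset(scn, seed=99)
        m = fit_zero_inflated(data, "negbin")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = ZeroInflatedNegativeBinomialP(
                data.outcome, data.count_design.to_numpy(),
                exog_infl=data.inflate_design.to_numpy(), inflation="logit", p=2,
            ).fit(disp=0, maxiter=200)
        assert m.loglik >= ref.llf - 1e-4

    def test_loglik_matches_latent_class_logsumexp(self, zi_dataset):
        # mixture formula vs log-sum-exp over the latent structural class
        data, _, _ = zi_dataset
        X = data.count_design.to_numpy()
        W = data.inflate_design.to_numpy()
        y = data.outcome.astype(float)
        _, _, loglik_obs, _ = _zi_machinery("poisson", X, W, y)
        rng = np.random.default_rng(0)
        for _ in range(100):
            theta = rng.normal(0, 0.7, X.shape[1] + W.shape[1])
            mu = np.exp(X @ theta[: X.shape[1]])
            eta = W @ theta[X.shape[1]:]
            logp = -np.logaddexp(0, -eta)
            log1mp = -np.logaddexp(0, eta)
            comp_zero = np.where(y == 0, logp, -np.inf)         # structural class
            comp_count = log1mp + log_pmf_arr("poisson", y, mu)  # count class
            ref = logsumexp(np.stack([comp_zero, comp_count]), axis=0)
            np.testing.assert_allclose(loglik_obs(theta), ref, atol=1e-10)

    def test_zip_loglik_dominates_poisson(self, zi_fit):
        m, data = zi_fit
        pr = fit_count_glm(data, "poisson")
        assert m.loglik >= pr.loglik  # ZIP nests PR at inflate intercept -> -inf

    def test_no_zeros_collapses_to_glm(self):
        rng = np.random.default_rng(13)
        n = 400
        g = rng.binomial(1, 0.5, n)
        y = rng.poisson(np.exp(1.5 + 0.3 * g)) + 1  # strictly positive
        data = make_dataset(y, g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_zero_inflated(data, "poisson")
        glm = fit_count_glm(data, "poisson")
        pred = predict_components(m, data)
        assert np.all(pred.pi < 1e-4)
        np.testing.assert_allclose(m.count_coefficients, glm.count_coefficients, atol=1e-4)

    def test_zinb_alpha_to_zero_reproduces_zip(self):
        scn = Scenario(n_subjects=700, structural_zero_prob=0.4, sampling_zero_target=0.15)
        data, _ = generate_dataset(scn, seed=31)
        zip_fit = fit_zero_inflated(data, "poisson")
        zinb_fit = fit_zero_inflated(data, "negbin")
        if zinb_fit.dispersion < 1e-4:
            np.testing.assert_allclose(
                zinb_fit.params[:-1], zip_fit.params, atol=1e-3)

    def test_parameter_recovery_large_n(self):
        scn = Scenario(n_subjects=20000, structural_zero_prob=0.3,
                       sampling_zero_target=0.18, inflate_group_coef=0.5)
        data, _ = generate_dataset(scn, seed=77)
        m = fit_zero_inflated(data, "poisson")
        from zicount import calibrate_count_intercept
        truth = {"const": calibrate_count_intercept(scn), "group": 0.4}
        se = m.se()
        for i, name in enumerate(m.count_names):
            assert abs(m.count_coefficients[i] - truth[name]) < 3 * se[i]

    def test_score_vanishes_at_optimum(self, zi_fit):
        m, _ = zi_fit
        _, g = m.negll_grad_fn(m.params)
        assert np.max(np.abs(g)) < 1e-6

    def test_robust_preserves_point_estimates(self, zi_dataset):
        data, _, _ = zi_dataset
        plain = fit_zero_inflated(data, "poisson")
        robust = fit_zero_inflated(data, "poisson", robust=True)
        np.testing.assert_allclose(robust.params, plain.params, atol=1e-10)
        assert robust.kind == "ZIRP" and robust.robust
        assert not np.allclose(robust.vcov, plain.vcov)


class TestHurdle:
    def test_logit_part_identical_to_logistic(self, zi_dataset):
        data, _, _ = zi_dataset
        h = fit_hurdle(data, "poisson")
        lr = fit_logistic(data, design="inflate")
        np.testing.assert_allclose(h.inflate_coefficients, lr.params, atol=1e-8)

    def test_total_loglik_is_exact_sum_of_parts(self, zi_dataset):
        data, _, _ = zi_dataset
        h = fit_hurdle(data, "poisson")
        lr = fit_logistic(data, design="inflate")
        pos = data.outcome > 0
        trunc_ll = h.loglik_obs[pos].sum() - lr.loglik_obs[pos].sum()
        assert h.loglik == pytest.approx(lr.loglik + trunc_ll, abs=1e-9)

    def test_truncated_poisson_recovery(self):
        rng = np.random.default_rng(41)
        n = 10000
        g = rng.binomial(1, 0.5, n)
        mu = np.exp(0.5 + 0.4 * g)
        # draw from the zero-truncated Poisson by rejection
        y = rng.poisson(mu)
        while (y == 0).any():
            idx = y == 0
            y[idx] = rng.poisson(mu[idx])
        # pad a handful of zeros in each group so the hurdle binary part is
        # well defined; they do not enter the truncated count likelihood
        data = make_dataset(np.concatenate([y, np.zeros(100, dtype=int)]),
                            np.concatenate([g, np.tile([0, 1], 50)]))
        m = fit_hurdle(data, "poisson")
        j = m.count_names.index("group")
        assert abs(m.count_coefficients[j] - 0.4) < 3 * m.se()[j]

    def test_all_positive_counts_rejected(self):
        y = np.arange(1, 30)
        g = np.tile([0.0, 1.0], 15)[:29]
        with pytest.raises(ValueError, match="degenerate"):
            fit_hurdle(make_dataset(y, g), "poisson")


class TestPredictComponents:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(55)
        y = (rng.poisson(1.0, 500) * rng.binomial(1, 0.5, 500))
        data = make_dataset(y, rng.binomial(1, 0.5, 500))
        m = fit_zero_inflated(data, "poisson")
        pred = predict_components(m, data)
        np.testing.assert_allclose(
            pred.prob_zero, pred.pi + (1 - pred.pi) * np.exp(-pred.mu), atol=1e-12)
        np.testing.assert_allclose(pred.prob_zero + pred.prob_pos, 1.0, atol=1e-12)
        np.testing.assert_allclose(pred.expected_count, (1 - pred.pi) * pred.mu, atol=1e-12)
        assert np.all((pred.structural_posterior >= 0) & (pred.structural_posterior <= 1))

    def test_fitted_expected_counts_sum_to_observed(self, zi_fit):
        m, data = zi_fit
        pred = predict_components(m, data)
        assert pred.expected_count.sum() == pytest.approx(data.outcome.sum(), rel=1e-3)

    def test_structural_posterior_tracks_generator_labels(self, zi_dataset):
        data, labels, scn = zi_dataset
        m = fit_zero_inflated(data, "poisson")
        pred = predict_components(m, data)
        zeros = data.outcome == 0
        # among observed zeros the average posterior should match the true
        # fraction that is structural
        true_frac = labels.loc[zeros, "structural"].mean()
        assert pred.structural_posterior[zeros].mean() == pytest.approx(true_frac, abs=0.05)

    def test_design_mismatch_raises(self, zi_fit):
        m, data = zi_fit
        bad = data.take(np.arange(data.n_subjects))
        bad.count_design.columns = ["const", "grp"]
        with pytest.raises(ValueError, match="design"):
            predict_components(m, bad)
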