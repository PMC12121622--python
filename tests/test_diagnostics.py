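"""Excess-zero / dispersion test battery and the selection flowchart."""

import warnings

import numpy as np
import pytest

from zicount import (Scenario, dispersion_tests, fit_count_glm, fit_hurdle,
                     fit_zero_inflated, generate_dataset, gof_chisq,
                     information_criteria, remove_excess_zeros,
                     score_test_zero_inflation, select_model_flowchart,
                     vuong_test_corrected)
from zicount.mixture import predict_components

from conftest import make_dataset


class TestScoreTest:
    def test_formula_against_manual_computation(self, small_counts):
        pr = fit_count_glm(small_counts, "poisson")
        res = score_test_zero_inflation(pr, small_counts)
        y = small_counts.outcome
        mu = np.exp(small_counts.count_design.to_numpy() @ pr.count_coefficients)
        p0 = np.exp(-mu)
        num = np.sum(((y == 0) - p0) / p0) ** 2
        den = np.sum((1 - p0) / p0) - len(y) * y.mean()
        assert res.statistic == pytest.approx(num / den, rel=1e-12)
        assert res.df == 1

    def test_statistic_increases_when_zeros_injected(self, small_counts):
        pr = fit_count_glm(small_counts, "poisson")
        base = score_test_zero_inflation(pr, small_counts)
        zeros = np.where(small_counts.outcome == 0)[0]
        doubled = small_counts.take(
            np.concatenate([np.arange(small_counts.n_subjects), zeros]))
        res2 = score_test_zero_inflation(fit_count_glm(doubled, "poisson"), doubled)
        assert res2.statistic > base.statistic

    def test_significant_on_zero_inflated_data(self, zi_dataset):
        data, _, _ = zi_dataset
        pr = fit_count_glm(data, "poisson")
        res = score_test_zero_inflation(pr, data)
        assert res.p_value < 1e-6


class TestVuong:
    def test_zip_favored_on_inflated_data(self, zi_dataset):
        data, _, _ = zi_dataset
        pr = fit_count_glm(data, "poisson")
        zip_fit = fit_zero_inflated(data, "poisson")
        res = vuong_test_corrected(zip_fit, pr, correction="AIC")
        assert res.statistic > 2 and res.p_value < 0.05

    def test_identical_models_degenerate_zero(self, small_counts):
        pr = fit_count_glm(small_counts, "poisson")
        res = vuong_test_corrected(pr, pr, correction="none")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_aic_correction_shrinks_statistic(self, zi_dataset):
        data, _, _ = zi_dataset
        pr = fit_count_glm(data, "poisson")
        zi = fit_zero_inflated(data, "poisson")
        none = vuong_test_corrected(zi, pr, correction="none")
        aic = vuong_test_corrected(zi, pr, correction="AIC")
        assert aic.statistic < none.statistic  # penalty works against the bigger model

    def test_mismatched_n_raises(self, zi_dataset, small_counts):
        data, _, _ = zi_dataset
        with pytest.raises(ValueError):
            vuong_test_corrected(fit_zero_inflated(data, "poisson"),
                                 fit_count_glm(small_counts, "poisson"))


class TestExcessZeroRemoval:
    def test_removed_fraction_matches_structural_rate(self, zi_dataset):
        data, labels, scn = zi_dataset
        zi = fit_zero_inflated(data, "poisson")
        reduced = remove_excess_zeros(data, zi)
        removed_frac = 1 - reduced.n_subjects / data.n_subjects
        assert removed_frac == pytest.approx(scn.structural_zero_prob, abs=0.06)

    def test_no_structural_zeros_identity(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(3.0, 300) + 1  # no zeros at all
        g = rng.binomial(1, 0.5, 300)
        data = make_dataset(y, g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zi = fit_zero_inflated(data, "poisson")
        reduced = remove_excess_zeros(data, zi)
        assert reduced.n_subjects == data.n_subjects

    def test_original_untouched_and_only_zeros_removed(self, zi_dataset):
        data, _, _ = zi_dataset
        n_before = data.n_subjects
        zi = fit_zero_inflated(data, "poisson")
        reduced = remove_excess_zeros(data, zi)
        assert data.n_subjects == n_before
        removed = n_before - reduced.n_subjects
        assert np.sum(data.outcome == 0) - np.sum(reduced.outcome == 0) == removed


class TestDispersion:
    def test_overdispersed_detected(self):
        rng = np.random.default_rng(9)
        n = 1000
        g = rng.binomial(1, 0.5, n)
        lam = rng.gamma(1.0, np.exp(0.5 + 0.3 * g))  # NB alpha = 1
        y = rng.poisson(lam)
        aux, boundary = dispersion_tests(make_dataset(y, g))
        assert aux.statistic > 0 and aux.p_value < 0.01
        assert boundary.p_value < 0.01

    def test_equidispersed_not_flagged(self):
        rng = np.random.default_rng(10)
        n = 1000
        g = rng.binomial(1, 0.5, n)
        y = rng.poisson(np.exp(0.5 + 0.3 * g))
        aux, boundary = dispersion_tests(make_dataset(y, g))
        assert aux.p_value > 0.05
        assert boundary.p_value > 0.05


class TestGofAndIC:
    def test_zip_fits_better_than_poisson_on_inflated_data(self, zi_dataset):
        data, _, _ = zi_dataset
        pr = fit_count_glm(data, "poisson")
        zi = fit_zero_inflated(data, "poisson")
        g_pr = gof_chisq(pr, data)
        g_zi = gof_chisq(zi, data)
        assert g_pr.statistic > g_zi.statistic
        assert g_pr.p_value < 0.001
        assert g_zi.p_value > 0.01

    def test_invariant_to_record_order(self, zi_dataset):
        data, _, _ = zi_dataset
        zi = fit_zero_inflated(data, "poisson")
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n_subjects)
        g1 = gof_chisq(zi, data)
        g2 = gof_chisq(zi, data.take(perm))
        assert g1.statistic == pytest.approx(g2.statistic, rel=1e-12)

    def test_expected_cells_sum_to_n(self, zi_dataset):
        from zicount.diagnostics import _cell_probabilities
        data, _, _ = zi_dataset
        for fitter, fam in [(fit_zero_inflated, "poisson"), (fit_hurdle, "poisson")]:
            m = fitter(data, fam)
            P = _cell_probabilities(m, data, 6)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_information_criteria_formulas(self, small_counts):
        m = fit_count_glm(small_counts, "poisson")
        ic = information_criteria(m)
        k, n = m.n_params, m.n_obs
        assert ic["AIC"] == pytest.approx(-2 * ic["LL"] + 2 * k)
        assert ic["BIC"] == pytest.approx(-2 * ic["LL"] + k * np.log(n))


class TestFlowchart:
    def test_plain_poisson_data_selects_single_distribution(self):
        rng = np.random.default_rng(17)
        n = 1500
        g = rng.binomial(1, 0.5, n)
        y = rng.poisson(np.exp(0.2 + 0.3 * g))
        report = select_model_flowchart(make_dataset(y, g), zero_type="mixed")
        assert report.recommended_model in ("PR", "RP")
        assert "absent" in report.rationale[0]

    def test_mixed_zeros_selects_inflated_family(self, zi_dataset):
        data, _, _ = zi_dataset
        report = select_model_flowchart(data, zero_type="mixed")
        assert report.recommended_model in ("ZIP", "ZIRP", "ZINB")
        assert report.recommended_model in report.fit_table["model"].values

    def test_structural_zeros_select_hurdle_family(self, zi_dataset):
        data, _, _ = zi_dataset
        report = select_model_flowchart(data, zero_type="structural")
        assert report.recommended_model.startswith("ZH")

    def test_deterministic(self, zi_dataset):
        data, _, _ = zi_dataset
        r1 = select_model_flowchart(data, zero_type="mixed")
        r2 = select_model_flowchart(data, zero_type="mixed")
        assert r1.recommended_model == r2.recommended_model
        assert r1.rationale == r2.rationale

    def test_zero_type_without_zeros_rejected(self):
        y = np.arange(1, 40)
        g = np.tile([0.0, 1.0], 20)[:39]
        with pytest.raises(ValueError):
            select_model_flowchart(make_dataset(y, g), zero_type="mixed")
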