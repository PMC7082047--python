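import math

import numpy as np
import pytest

from triocc import (
    DataValidationError,
    McmcConfig,
    ModelSpec,
    SimulationScenario,
    assess_model,
    bayesian_p_value,
    compare_models,
    covariate_significance,
    cpo_criterion,
    deviance_residuals,
    gelman_rubin,
    hdi,
    kfold_cv,
    prior_sensitivity,
    simulate_dataset,
    waic,
)
from triocc.assessment import (
    AssessmentResult,
    detection_scores,
    pointwise_loglik,
    rhat_from_chains,
)
from triocc.sampler import PosteriorSamples


def _fake_samples(ll_shape_draws):
    """Not a sampler product: hand-written draws for score arithmetic."""
    return ll_shape_draws


class TestWaicAndCpoHandOracles:
    # three hand-written draws on a 2-unit problem
    LL = np.log(np.array([[0.5, 0.2], [0.25, 0.4], [0.4, 0.1]]))  # (T=3, U=2)

    def _hand_waic(self):
        L = np.exp(self.LL)
        lppd = np.log(L.mean(axis=0)).sum()
        p_waic = self.LL.var(axis=0, ddof=1).sum()
        return -2 * (lppd - p_waic)

    def test_waic_matches_hand_computation(self):
        got = waic(None, None, None, None, loglik_matrix=self.LL[:, None, :])
        assert got == pytest.approx(self._hand_waic(), abs=1e-12)

    def test_waic_degenerate_posterior_has_zero_penalty(self):
        ll = np.tile(self.LL[:1], (4, 1))
        got = waic(None, None, None, None, loglik_matrix=ll[:, None, :])
        assert got == pytest.approx(-2 * self.LL[0].sum(), abs=1e-12)

    def test_cpo_harmonic_mean_arithmetic(self):
        # 2 draws with L = {0.5, 0.25}: CPO = 1/3, contribution 3
        ll = np.log(np.array([[0.5], [0.25]]))[:, None, :]
        got = cpo_criterion(None, None, None, None, loglik_matrix=ll)
        assert got == pytest.approx(3.0, abs=1e-12)

    def test_cpo_degenerate_posterior_reduces_to_inverse_likelihood(self):
        ll = np.tile(self.LL[:1], (5, 1))[:, None, :]
        got = cpo_criterion(None, None, None, None, loglik_matrix=ll)
        assert got == pytest.approx((1 / np.exp(self.LL[0])).sum(), abs=1e-10)

    def test_cpo_always_positive_and_log_variant(self):
        got = cpo_criterion(None, None, None, None, loglik_matrix=self.LL[:, None, :])
        assert got > 0
        got_log = cpo_criterion(None, None, None, None, loglik_matrix=self.LL[:, None, :],
                                use_log=True)
        L = np.exp(self.LL)
        assert got_log == pytest.approx(np.log((1 / L).mean(axis=0)).sum(), abs=1e-12)


class TestScoringRules:
    def test_brier_and_log_hand_example(self):
        brier, log_score = detection_scores([1, 0], [0.8, 0.3])
        assert brier == pytest.approx(0.2**2 + 0.3**2, abs=1e-12)
        assert log_score == pytest.approx(-(math.log(0.8) + math.log(0.7)), abs=1e-12)

    def test_perfect_prediction_scores_zero(self):
        brier, log_score = detection_scores([1, 0, 1], [1 - 1e-12, 1e-12, 1 - 1e-12])
        assert brier == pytest.approx(0.0, abs=1e-9)
        assert log_score == pytest.approx(0.0, abs=1e-9)

    def test_scores_are_proper(self):
        """Scoring with the true generative probabilities must beat perturbed
        probabilities in expectation (propriety), checked by simulation."""
        rng = np.random.default_rng(0)
        p_true = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p_true).astype(float)
        p_bad = np.clip(p_true + rng.normal(0, 0.25, 500), 0.01, 0.99)
        for scores in (detection_scores(y, p_true), ):
            pass
        b_true, l_true = detection_scores(y, p_true)
        b_bad, l_bad = detection_scores(y, p_bad)
        assert b_true < b_bad
        assert l_true < l_bad


class TestGelmanRubin:
    def test_formula_arithmetic(self):
        # identical chains (1,2,3): B=0, W=1, n=3 -> sqrt(2/3)
        assert rhat_from_chains([[1, 2, 3], [1, 2, 3]]) == pytest.approx(
            math.sqrt(2 / 3), abs=1e-12
        )

    def test_separated_chains_blow_up(self):
        assert rhat_from_chains([[0, 0, 0, 1], [10, 10, 10, 11]]) > 1.1 * 3

    def test_degenerate_chains_raise(self):
        with pytest.raises(DataValidationError, match="degenerate"):
            rhat_from_chains([[1.0, 1.0], [1.0, 1.0]])

    def test_well_mixed_fit_converges(self, small_fit):
        samples, *_ = small_fit
        assert gelman_rubin(samples, "mu_lp") < 1.1


class TestHdi:
    def test_point_mass(self):
        assert hdi([3.0] * 25) == (3.0, 3.0)

    def test_uniform_draws_first_window(self):
        lo, hi = hdi(np.arange(1, 101), mass=0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(4)
        draws = rng.gamma(2.0, 1.0, 173)
        x = np.sort(draws)
        m = math.ceil(0.9 * x.size)
        best = min(
            ((x[j + m - 1] - x[j], (x[j], x[j + m - 1])) for j in range(x.size - m + 1)),
            key=lambda t: t[0],
        )[1]
        assert hdi(draws, mass=0.9) == best

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            draws = rng.lognormal(0, 1, 200)
            lo, hi = hdi(draws)
            qlo, qhi = np.quantile(draws, [0.025, 0.975], method="inverted_cdf")
            assert hi - lo <= qhi - qlo + 1e-12

    def test_empty_raises(self):
        with pytest.raises(DataValidationError):
            hdi([])


class TestCovariateSignificance:
    def _samples_with(self, draws):
        return PosteriorSamples(
            draws={"mu_beta3": np.asarray(draws)[None, :, None, None]},
            species_labels=[], n_observed_species=0, spec=ModelSpec(),
            config=McmcConfig(n_iterations=10, burn_in=0, thin=1),
        )

    def test_all_positive_is_significant(self):
        s = self._samples_with(np.linspace(0.5, 2.0, 50))
        assert covariate_significance(s, "mu_beta3")["significant"]

    def test_symmetric_about_zero_is_not(self):
        s = self._samples_with(np.linspace(-1, 1, 50))
        assert not covariate_significance(s, "mu_beta3")["significant"]


class TestDevianceResiduals:
    def test_closed_form_unit_value(self, small_fit):
        # a unit with loglik log(0.875) and obs < expected has residual
        # -sqrt(-2 log 0.875) ~ -0.5168
        assert -math.copysign(math.sqrt(-2 * math.log(0.875)), 1) == pytest.approx(
            -0.51676, abs=1e-4
        )
        samples, data, cov, spec = small_fit
        resid = deviance_residuals(samples, data, cov, spec)
        assert resid.shape == (data.n_observed_species, data.n_sites)
        assert np.isfinite(resid).all()

    def test_sign_matches_observed_minus_expected(self, small_fit):
        samples, data, cov, spec = small_fit
        from triocc.assessment import _draw_params
        from triocc.likelihood import build_design, expected_detections_matrix, p_eta, psi_eta, theta_eta

        resid = deviance_residuals(samples, data, cov, spec)
        K = data.n_observed_species
        obs = (data.y[..., :K] * data.observed_mask[..., :K]).sum(axis=(1, 2))
        # posterior-mean expectation as reference sign for clear-cut units
        design = build_design(data.shape, cov, spec)
        E = np.zeros_like(obs, dtype=float)
        for t in range(samples.n_total_draws):
            params = _draw_params(samples, t, K)
            E += expected_detections_matrix(psi_eta(params, design),
                                            theta_eta(params, design),
                                            p_eta(params, design),
                                            data.observed_mask[..., :K])
        E /= samples.n_total_draws
        diff = (obs - E).T
        clear = np.abs(diff) > 1.0
        assert (np.sign(resid[clear]) == np.sign(diff[clear])).all()


class TestBayesianPValue:
    def test_deterministic_given_seed(self, small_fit):
        samples, data, cov, spec = small_fit
        ll = pointwise_loglik(samples, data, cov, spec)
        p1 = bayesian_p_value(samples, data, cov, spec, seed=3, loglik_matrix=ll)
        p2 = bayesian_p_value(samples, data, cov, spec, seed=3, loglik_matrix=ll)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0

    def test_gross_parameter_mismatch_yields_extreme_p_value(self):
        """A posterior concentrated on parameters that badly mismatch the
        data must produce an extreme p-value (observed deviance far beyond
        what the model replicates), while a posterior concentrated near the
        generating parameters must not."""
        scn = SimulationScenario(I=15, J=2, R=3, K_true=8, mu_lpsi=-1.2,
                                 sigma_lpsi=0.3, mu_ltheta=1.0, sigma_ltheta=0.2,
                                 mu_lp=-1.2, sigma_lp=0.2, mu_beta3=0.0,
                                 sigma_beta3=0.0, mu_beta1=0.0, sigma_beta1=0.0,
                                 include_amplicon=False, seed=11)
        data, cov, _ = simulate_dataset(scn)

        def point_posterior(lpsi, ltheta, lp):
            K = data.n_observed_species
            S = 120
            draws = {"lpsi": np.full((1, S, K), lpsi),
                     "ltheta": np.full((1, S, K), ltheta),
                     "lp": np.full((1, S, K), lp)}
            return PosteriorSamples(
                draws=draws, species_labels=data.species_labels,
                n_observed_species=K, spec=ModelSpec(),
                config=McmcConfig(n_iterations=S, burn_in=0, thin=1),
            )

        spec = ModelSpec()
        p_bad = bayesian_p_value(point_posterior(2.2, 2.2, 2.2), data, cov, spec, seed=1)
        p_near = bayesian_p_value(point_posterior(-1.2, 1.0, -1.2), data, cov, spec, seed=1)
        assert p_bad < 0.05  # sparse data scored at psi=theta=p~0.9: misfit
        assert abs(p_near - 0.5) < abs(p_bad - 0.5)


class TestKfoldCv:
    def test_seeded_folds_are_reproducible(self, small_dataset):
        data, cov, _ = small_dataset
        spec = ModelSpec(psi_covariates=("water_depth",))
        cfg = McmcConfig(n_chains=1, n_iterations=300, burn_in=100, thin=2, seed=0)
        r1 = kfold_cv(data, cov, spec, k=3, mcmc_config=cfg, seed=9)
        r2 = kfold_cv(data, cov, spec, k=3, mcmc_config=cfg, seed=9)
        assert r1.brier == r2.brier and r1.log_score == r2.log_score
        assert r1.n_cells == int(data.observed_mask.sum())
        assert r1.brier > 0 and r1.log_score > 0

    def test_bad_k_raises(self, small_dataset):
        data, cov, _ = small_dataset
        with pytest.raises(DataValidationError):
            kfold_cv(data, cov, ModelSpec(), k=1)
        with pytest.raises(DataValidationError):
            kfold_cv(data, cov, ModelSpec(), k=data.n_sites + 1)


class TestCompareModels:
    def _result(self, label, **crit):
        return AssessmentResult(label=label, data_fingerprint="abc", **crit)

    def test_dominant_model_wins(self):
        a = self._result("A", waic=1, cpo_criterion=1, cv_brier=1, cv_log_score=1)
        b = self._result("B", waic=2, cpo_criterion=2, cv_brier=2, cv_log_score=2)
        out = compare_models([a, b])
        assert out["consensus"] == "A"

    def test_split_verdict_resolved_by_majority_with_note(self):
        a = self._result("A", waic=1, cpo_criterion=1, cv_brier=5, cv_log_score=1)
        b = self._result("B", waic=2, cpo_criterion=2, cv_brier=1, cv_log_score=2)
        out = compare_models([a, b])
        assert out["consensus"] == "A"
        assert any("majority" in n for n in out["notes"])

    def test_full_tie_is_indeterminate(self):
        a = self._result("A", waic=1, cpo_criterion=2, cv_brier=None, cv_log_score=None)
        b = self._result("B", waic=2, cpo_criterion=1, cv_brier=None, cv_log_score=None)
        out = compare_models([a, b])
        assert out["consensus"] == "indeterminate"

    def test_different_datasets_rejected(self):
        a = self._result("A", waic=1)
        b = AssessmentResult(label="B", waic=2, data_fingerprint="xyz")
        with pytest.raises(DataValidationError):
            compare_models([a, b])


class TestPriorSensitivity:
    def test_informative_data_shrugs_off_prior_change(self):
        from triocc import PriorConfig

        # every level well replicated so all hyperparameters are identified
        scn = SimulationScenario(I=20, J=4, R=4, K_true=15, mu_lpsi=0.0,
                                 sigma_lpsi=0.6, mu_ltheta=1.0, sigma_ltheta=0.4,
                                 mu_lp=0.0, sigma_lp=0.4, mu_beta3=1.0,
                                 sigma_beta3=0.3, mu_beta1=0.0, sigma_beta1=0.0,
                                 include_amplicon=False, seed=8)
        data, cov, _ = simulate_dataset(scn)
        spec = ModelSpec(psi_covariates=("water_depth",))
        cfg = McmcConfig(n_chains=1, n_iterations=1200, burn_in=500, thin=2, seed=1)
        grid = [PriorConfig(mu_var=10.0), PriorConfig(mu_var=100.0)]
        report = prior_sensitivity(data, cov, spec, grid, mcmc_config=cfg, seed=2)
        mus = report[report["parameter"].str.startswith("mu_") & (report["prior"] == 1)]
        assert (mus["shift_from_first"] < 0.5).all()
        assert mus["hdi_overlaps_first"].all()


class TestAssessModel:
    def test_full_assessment_is_finite_and_repeatable(self, small_fit):
        samples, data, cov, spec = small_fit
        r1 = assess_model(samples, data, cov, spec, seed=13)
        r2 = assess_model(samples, data, cov, spec, seed=13)
        assert r1.waic == r2.waic
        assert r1.cpo_criterion == r2.cpo_criterion
        assert r1.bayesian_p_value == r2.bayesian_p_value
        for v in (r1.waic, r1.cpo_criterion, r1.bayesian_p_value):
            assert np.isfinite(v)

    def test_wrong_data_rejected(self, small_fit):
        samples, data, cov, spec = small_fit
        other = data.subset_sites(np.arange(data.n_sites - 1))
        with pytest.raises(DataValidationError):
            pointwise_loglik(samples, other, cov, spec)
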