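import numpy as np
import pytest

from triocc import (
    CovariateSet,
    DataValidationError,
    DetectionArray,
    McmcConfig,
    ModelSpec,
    check_augmentation_sufficiency,
    posterior_richness,
    run_mcmc,
)
from triocc._util import inv_logit
from triocc.likelihood import build_design
from triocc.sampler import (
    ChainState,
    a_full_conditional_prob,
    w_full_conditional_prob,
    z_full_conditional_prob,
)


class TestFullConditionals:
    def test_z_conditional_closed_forms(self):
        assert z_full_conditional_prob([0, 1], 0.5, [0.5, 0.5]) == 1.0
        # all w = 0: 0.5*0.25 / (0.5*0.25 + 0.5) = 0.2
        assert z_full_conditional_prob([0, 0], 0.5, [0.5, 0.5]) == pytest.approx(0.2, abs=1e-15)
        assert z_full_conditional_prob([0, 0], 0.0, [0.5, 0.5]) == 0.0

    def test_w_conditional_closed_forms(self):
        assert w_full_conditional_prob([0, 0], 1, 0.5, [0.5, 0.5]) == pytest.approx(0.2, abs=1e-15)
        assert w_full_conditional_prob([0, 1], 1, 0.5, [0.5, 0.5]) == 1.0
        assert w_full_conditional_prob([0, 0], 0, 0.5, [0.5, 0.5]) == 0.0
        with pytest.raises(DataValidationError):
            w_full_conditional_prob([1], 0, 0.5, [0.5])

    def test_inclusion_conditional_matches_unit_likelihood_closed_form(self):
        # I=J=R=1, psi=theta=p=0.5: all-zero unit likelihood 0.875
        got = a_full_conditional_prob(0.5, [0.5], [[0.5]], [[[0.5]]])
        assert got == pytest.approx(0.5 * 0.875 / (0.5 * 0.875 + 0.5), abs=1e-12)
        assert a_full_conditional_prob(1.0, [0.5], [[0.5]], [[[0.5]]]) == 1.0


def _fixed_state(y, M=0, spec=None, seed=0):
    data = DetectionArray(y=y)
    spec = spec or ModelSpec(augmentation_M=M)
    if M:
        data = data.augment(M)
    cov = CovariateSet()
    design = build_design(data.shape, cov, spec)
    rng = np.random.default_rng(seed)
    K = data.n_species
    return ChainState(data, design, spec, np.zeros(K, dtype=np.intp), 1, rng), data


class TestGibbsCorrectness:
    def test_toy_occupancy_posterior_matches_bayes(self):
        """Two sites, one species detected only at the second: the sampler's
        marginal P(z=1 | all-zero history) at the first site must match the
        analytic posterior psi*m0 / (psi*m0 + 1-psi), with m0 the all-zero
        capture-detection likelihood, at fixed psi = theta = p = 0.5."""
        y = np.zeros((2, 2, 2, 1), dtype=np.int8)
        y[1, 0, 0, 0] = 1
        st, _ = _fixed_state(y, seed=13)
        hits = 0
        n = 40000
        for _ in range(n):
            st.update_latent_states()
            hits += int(st.z[0, 0])
        # per-sample all-zero likelihood: theta*(1-p)^2 + (1-theta) = 0.625
        # two samples -> m0 = 0.390625
        m0 = 0.625**2
        expected = 0.5 * m0 / (0.5 * m0 + 0.5)
        assert hits / n == pytest.approx(expected, abs=0.01)

    def test_empirical_inclusion_probability_matches_closed_form(self):
        y = np.ones((1, 1, 1, 1), dtype=np.int8)
        st, _ = _fixed_state(y, M=2)
        hits = 0
        n = 30000
        for _ in range(n):
            st.omega = 0.5  # pin Omega: isolate the a_k conditional
            st.update_latent_states()
            hits += int(st.a[1])
        assert hits / n == pytest.approx(0.4667, abs=0.01)


class TestMetropolisBlocks:
    def test_detection_intercept_targets_grid_oracle(self):
        """With latent states pinned at w = z = 1 the lp conditional is a
        Bernoulli likelihood x normal prior; compare the MH chain's posterior
        mean of p = logit^-1(lp) against numerical integration."""
        rng = np.random.default_rng(5)
        y = (rng.random((1, 1, 40, 1)) < 0.3).astype(np.int8)
        st, data = _fixed_state(y, seed=11)
        st.z[:] = 1
        st.w[:] = 1
        mu0, sd0 = 0.0, 2.0
        st.mu["lp"][:] = mu0
        st.sigma["lp"][:] = sd0
        draws = []
        for it in range(6000):
            st.update_species_coefficients()
            if it % 20 == 19:
                st.adapt(it // 20 + 1)
            if it >= 1000:
                draws.append(st.coef["lp"][0])
        # grid oracle
        grid = np.linspace(-8, 8, 20001)
        k = int(y.sum())
        n = y.size
        logpost = (k * np.log(inv_logit(grid)) + (n - k) * np.log1p(-inv_logit(grid))
                   - 0.5 * ((grid - mu0) / sd0) ** 2)
        wgt = np.exp(logpost - logpost.max())
        oracle = float((inv_logit(grid) * wgt).sum() / wgt.sum())
        assert np.mean(inv_logit(np.array(draws))) == pytest.approx(oracle, abs=0.01)

    def test_prior_dominates_when_sigma_shrinks(self):
        y = np.ones((1, 1, 2, 1), dtype=np.int8)
        st, _ = _fixed_state(y, seed=2)
        st.z[:] = 1
        st.w[:] = 1
        st.mu["lpsi"][:] = 3.0
        st.sigma["lpsi"][:] = 1e-3
        for _ in range(300):
            st.update_species_coefficients()
        assert st.coef["lpsi"][0] == pytest.approx(3.0, abs=0.05)


class TestHyperparameterUpdates:
    def test_conjugate_mu_matches_precision_weighted_posterior(self):
        y = np.zeros((1, 1, 1, 5), dtype=np.int8)
        y[0, 0, 0, :] = 1
        st, _ = _fixed_state(y, seed=9)
        coefs = np.array([0.4, -1.2, 2.0, 0.3, 0.9])
        st.coef["lpsi"] = coefs.copy()
        sigma = 0.7
        draws = []
        for _ in range(20000):
            st.sigma["lpsi"][:] = sigma  # pin sigma; mu draw is exact Gibbs
            st.coef["lpsi"] = coefs.copy()
            st.update_hyperparameters()
            draws.append(st.mu["lpsi"][0, 0])
        v0, m0, n = 10.0, 0.0, 5
        post_var = 1 / (1 / v0 + n / sigma**2)
        post_mean = post_var * (m0 / v0 + coefs.sum() / sigma**2)
        assert np.mean(draws) == pytest.approx(post_mean, abs=0.01)
        assert np.var(draws) == pytest.approx(post_var, rel=0.05)

    def test_sigma_respects_uniform_support(self, small_fit):
        samples, *_ = small_fit
        for name in samples.draws:
            if name.startswith("sigma_"):
                vals = samples.stacked(name)
                assert (vals >= 0).all() and (vals <= 5.0).all()


class TestRunMcmc:
    def test_bit_identical_reruns(self, small_dataset, small_scenario):
        data, cov, truth = small_dataset
        spec = small_scenario.model_spec()
        cfg = McmcConfig(n_chains=2, n_iterations=200, burn_in=50, thin=3, seed=123)
        s1 = run_mcmc(data, cov, spec, cfg)
        s2 = run_mcmc(data, cov, spec, cfg)
        for name in s1.draws:
            np.testing.assert_array_equal(s1.draws[name], s2.draws[name])
        assert s1.n_saved == cfg.n_saved == (200 - 50) // 3

    def test_draws_respect_latent_ordering(self, small_fit):
        samples, *_ = small_fit
        z = samples.draws["z"]
        w = samples.draws["w"]
        assert (w <= z[:, :, :, None, :]).all()

    def test_saturated_data_yields_high_occupancy(self):
        y = np.ones((4, 2, 2, 3), dtype=np.int8)
        data = DetectionArray(y=y)
        cfg = McmcConfig(n_chains=2, n_iterations=600, burn_in=200, thin=2, seed=5)
        s = run_mcmc(data, CovariateSet(), ModelSpec(), cfg)
        psi = inv_logit(s.stacked("lpsi"))
        assert psi.mean() > 0.85
        assert (s.draws["z"] == 1).all()

    def test_acceptance_rates_adapt_into_band(self, small_fit):
        samples, *_ = small_fit
        for name, rate in samples.acceptance.items():
            assert 0.2 <= rate <= 0.65, (name, rate)


class TestGroupedModel:
    def test_group_indexed_hyperparameters_track_their_groups(self):
        """Two groups with opposite occupancy regimes: the group-indexed
        community means must separate in the right direction."""
        from triocc import SimulationScenario, simulate_dataset

        scn = SimulationScenario(
            I=15, J=2, R=3, K_true=12, mu_ltheta=1.5, sigma_ltheta=0.3,
            mu_lp=0.5, sigma_lp=0.3, mu_beta1=0.0, sigma_beta1=0.0,
            mu_beta3=0.0, sigma_beta3=0.0, include_amplicon=False,
            sigma_lpsi=0.4,
            group_assignment={"high": 6, "low": 6},
            group_hyper={"high": {"mu_lpsi": 1.2}, "low": {"mu_lpsi": -1.2}},
        )
        data, cov, truth = simulate_dataset(scn, seed=31)
        detected = [s for s in data.species_labels]
        gmap = {s: truth["groups"][truth["species_labels"].index(s)] for s in detected}
        counts = {g: sum(v == g for v in gmap.values()) for g in set(gmap.values())}
        assert all(c >= 2 for c in counts.values())
        spec = ModelSpec(group_map=gmap)
        cfg = McmcConfig(n_chains=2, n_iterations=1200, burn_in=500, thin=2, seed=4)
        samples = run_mcmc(data, cov, spec, cfg)
        assert samples.group_labels == sorted(counts)
        mu = samples.stacked("mu_lpsi").reshape(samples.n_total_draws, -1)
        g_high = samples.group_labels.index("high")
        g_low = samples.group_labels.index("low")
        assert mu[:, g_high].mean() > mu[:, g_low].mean() + 0.5


@pytest.fixture(scope="module")
def augmented_fit():
    rng = np.random.default_rng(77)
    y = (rng.random((6, 2, 3, 8)) < 0.25).astype(np.int8)
    for k in range(8):
        if not y[..., k].any():
            y[0, 0, 0, k] = 1
    data = DetectionArray(y=y)
    spec = ModelSpec(augmentation_M=20)
    cfg = McmcConfig(n_chains=2, n_iterations=800, burn_in=300, thin=2, seed=21)
    return run_mcmc(data, CovariateSet(), spec, cfg), data


class TestAugmentedModel:
    def test_observed_species_always_included(self, augmented_fit):
        samples, data = augmented_fit
        a = samples.draws["a"]
        assert (a[:, :, : data.n_observed_species] == 1).all()

    def test_z_zero_whenever_excluded(self, augmented_fit):
        samples, _ = augmented_fit
        a = samples.draws["a"]
        z = samples.draws["z"]
        assert (z[:, :, :, :].transpose(0, 1, 3, 2)[a == 0] == 0).all()

    def test_richness_summary_counts_inclusions(self, augmented_fit):
        samples, data = augmented_fit
        summ = posterior_richness(samples)
        N = samples.stacked("a").sum(axis=1)
        assert summ["mean"] == pytest.approx(N.mean())
        assert summ["n_observed"] == data.n_observed_species
        assert summ["pmf"].sum() == pytest.approx(1.0)

    def test_sufficiency_rule_counts_tail_draws(self, augmented_fit):
        samples, _ = augmented_fit
        ok, report = check_augmentation_sufficiency(samples)
        N = samples.stacked("N")
        manual = float(np.mean(N >= samples.spec.augmentation_M - 1))
        assert report["tail_prob"] == pytest.approx(manual)
        assert ok == (manual < 0.01)

    def test_richness_requires_augmented_fit(self, small_fit):
        samples, *_ = small_fit
        with pytest.raises(DataValidationError):
            posterior_richness(samples)
        with pytest.raises(DataValidationError):
            check_augmentation_sufficiency(samples)

    def test_omega_pinned_at_one_forces_full_inclusion(self):
        y = np.ones((1, 1, 1, 1), dtype=np.int8)
        st, _ = _fixed_state(y, M=4, seed=1)
        for _ in range(50):
            st.omega = 1.0 - 1e-15
            st.update_latent_states()
            assert st.a.sum() == 4
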