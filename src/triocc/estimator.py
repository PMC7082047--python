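"""scikit-learn-style estimator facade over the occupancy sampler.

``MultiScaleOccupancy`` bundles model specification, covariate
standardization, MCMC settings and assessment into a single fit-shaped
object with ``get_params``/``set_params`` support, so it slots into
scikit-learn style experiment code.  The functional surface
(``run_mcmc``, ``assess_model``, ...) remains the primitive layer; the
estimator composes it.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._util import inv_logit
from .data import (
    CovariateSet,
    DataValidationError,
    DetectionArray,
    ModelSpec,
    PriorConfig,
    standardize_covariates,
)
from .likelihood import build_design, p_eta, psi_eta, theta_eta, total_marginal_loglik
from .sampler import (
    McmcConfig,
    check_augmentation_sufficiency,
    posterior_richness,
    run_mcmc,
)


class MultiScaleOccupancy(BaseEstimator):
    """Three-level multi-species occupancy model (occupancy -> capture ->
    detection) fitted by MCMC.

    Parameters
    ----------
    psi_covariates, theta_covariates, p_covariates : sequences of covariate
        names entering the occupancy, capture and detection links.
    augmentation_m : int
        0 fits known richness; otherwise the community is padded to this
        many species rows to estimate total richness.
    group_map : dict or None
        species label -> group (e.g. phylum); switches community
        hyperparameters to group-indexed.
    mu_prior_var, sigma_prior_upper : floats
        community hyperpriors mu ~ N(0, mu_prior_var) and
        sigma ~ Uniform(0, sigma_prior_upper).
    standardize : bool
        z-score continuous covariates before fitting (stored for
        back-transformation).
    n_chains, n_iterations, burn_in, thin, seed : MCMC settings.

    Attributes (after fit)
    ----------------------
    samples_ : PosteriorSamples of all species- and community-level draws.
    spec_    : the resolved ModelSpec.
    covariates_ : the (standardized) CovariateSet actually used.
    rhat_    : Gelman-Rubin diagnostic per community parameter.
    """

    def __init__(self, psi_covariates=(), theta_covariates=(), p_covariates=(),
                 augmentation_m=0, group_map=None, mu_prior_var=10.0,
                 sigma_prior_upper=5.0, standardize=True, n_chains=3,
                 n_iterations=50_000, burn_in=10_000, thin=10, seed=None,
                 label=""):
        self.psi_covariates = psi_covariates
        self.theta_covariates = theta_covariates
        self.p_covariates = p_covariates
        self.augmentation_m = augmentation_m
        self.group_map = group_map
        self.mu_prior_var = mu_prior_var
        self.sigma_prior_upper = sigma_prior_upper
        self.standardize = standardize
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.label = label

    # -- plumbing ----------------------------------------------------------

    def _make_spec(self) -> ModelSpec:
        return ModelSpec(
            psi_covariates=tuple(self.psi_covariates),
            theta_covariates=tuple(self.theta_covariates),
            p_covariates=tuple(self.p_covariates),
            augmentation_M=self.augmentation_m,
            group_map=self.group_map,
            priors=PriorConfig(mu_var=self.mu_prior_var,
                               sigma_upper=self.sigma_prior_upper),
            label=self.label,
        )

    def _make_config(self) -> McmcConfig:
        return McmcConfig(n_chains=self.n_chains, n_iterations=self.n_iterations,
                          burn_in=self.burn_in, thin=self.thin, seed=self.seed)

    # -- estimator API -----------------------------------------------------

    def fit(self, X: DetectionArray, y=None, covariates: CovariateSet | None = None):
        """Run the sampler on a DetectionArray (y is ignored; present for
        scikit-learn API compatibility)."""
        if not isinstance(X, DetectionArray):
            raise DataValidationError(
                "X must be a DetectionArray (build one with triocc.io.read_detection_table "
                "or triocc.simulate.simulate_dataset)"
            )
        cov = covariates if covariates is not None else CovariateSet()
        if self.standardize and (cov.site_continuous or cov.sample_continuous
                                 or cov.replicate_continuous):
            needs = any(name not in cov.standardization
                        for name in (list(cov.site_continuous)
                                     + list(cov.sample_continuous)
                                     + list(cov.replicate_continuous)))
            if needs:
                cov = standardize_covariates(cov, mask=X.observed_mask.any(axis=3))
        self.spec_ = self._make_spec()
        self.covariates_ = cov
        self.samples_ = run_mcmc(X, cov, self.spec_, self._make_config())
        self.data_shape_ = X.shape
        from .assessment import gelman_rubin

        self.rhat_ = {}
        if self.samples_.n_chains >= 2 and self.samples_.n_saved >= 2:
            for name in self.samples_.community_parameter_names():
                self.rhat_[name] = gelman_rubin(self.samples_, name)
        return self

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise DataValidationError("estimator is not fitted yet; call fit first")

    def predict_detection_proba(self, covariates: CovariateSet | None = None,
                                data_shape=None) -> np.ndarray:
        """Posterior-mean unconditional detection probability per cell,
        E[psi_ik * theta_ijk * p_ijrk], shape (I, J, R, K_observed)."""
        self._check_fitted()
        cov = covariates if covariates is not None else self.covariates_
        shape = data_shape or self.data_shape_
        design = build_design(shape, cov, self.spec_)
        from .assessment import _draw_params

        K = self.samples_.n_observed_species
        T = self.samples_.n_total_draws
        out = np.zeros(shape[:3] + (K,))
        for t in range(T):
            params = _draw_params(self.samples_, t, K)
            out += (
                inv_logit(psi_eta(params, design))[:, None, None, :]
                * inv_logit(theta_eta(params, design))[:, :, None, :]
                * inv_logit(p_eta(params, design))
            )
        return out / T

    def score(self, X: DetectionArray, y=None) -> float:
        """Posterior-mean marginal log-likelihood of the supplied data."""
        self._check_fitted()
        from .assessment import _draw_params

        design_cov = self.covariates_
        K = X.n_observed_species
        T = self.samples_.n_total_draws
        total = 0.0
        for t in range(T):
            params = _draw_params(self.samples_, t, K)
            total += total_marginal_loglik(X, params, design_cov, self.spec_)
        return total / T

    def assess(self, X: DetectionArray, seed=None, cv_k=None, cv_config=None):
        """Full assessment of the fitted model on its data."""
        self._check_fitted()
        from .assessment import assess_model

        return assess_model(self.samples_, X, self.covariates_, self.spec_,
                            seed=seed, cv_k=cv_k, cv_config=cv_config,
                            label=self.label or self.spec_.label_or_formula())

    def estimate_richness(self, mass=0.95):
        self._check_fitted()
        return posterior_richness(self.samples_, mass=mass)

    def augmentation_sufficient(self):
        self._check_fitted()
        return check_augmentation_sufficiency(self.samples_)


def fit_model(data, covariates=None, spec: ModelSpec | None = None,
              config: McmcConfig | None = None) -> MultiScaleOccupancy:
    """Functional one-liner: build and fit a MultiScaleOccupancy estimator."""
    spec = spec or ModelSpec()
    config = config or McmcConfig()
    est = MultiScaleOccupancy(
        psi_covariates=spec.psi_covariates,
        theta_covariates=spec.theta_covariates,
        p_covariates=spec.p_covariates,
        augmentation_m=spec.augmentation_M,
        group_map=spec.group_map,
        mu_prior_var=spec.priors.mu_var,
        sigma_prior_upper=spec.priors.sigma_upper,
        n_chains=config.n_chains,
        n_iterations=config.n_iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
        label=spec.label,
    )
    return est.fit(data, covariates=covariates)


__all__ = ["MultiScaleOccupancy", "fit_model"]
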