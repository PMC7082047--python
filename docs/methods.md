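# Methods

## Model

`triocc` fits a hierarchical occupancy model with three coupled Bernoulli
levels to binary detection data `y[i,j,r,k]` over sites, biological
samples, technical replicates and species:

    z_ik   ~ Bernoulli(psi_ik)            -- DNA of species k occurs at site i
    w_ijk  ~ Bernoulli(theta_ijk * z_ik)  -- DNA captured in sample j
    y_ijrk ~ Bernoulli(p_ijrk * w_ijk)    -- detected in replicate r

Assumptions: no false positives (a detection implies capture and
occupancy); closure within the survey (a single season, one `z` per
site × species); replicates conditionally independent given the latent
states; species exchangeable given their community (or group) membership.

Covariates enter on the logit scale: site-level continuous covariates on
occupancy (`beta3`), sample-level on capture (`btheta`), and replicate-level
continuous (`beta1`) plus at most one categorical covariate (`beta2`, one
effect per level) on detection. Continuous covariates are z-scored (sample
sd, n−1) with the (mean, sd) stored for back-transformation; a constant
covariate is rejected. All categorical level effects are drawn
hierarchically from one community normal without a corner constraint; the
hierarchical prior resolves the weak identifiability, and contrasts rather
than raw levels are the interpretable summaries.

Species coefficients follow community normals, e.g.
`lpsi_k ~ N(mu_lpsi, sigma_lpsi)`, one (mu, sigma) pair per coefficient
family — or per group when a species→group mapping (e.g. phylum) is
supplied, in which case every group must contain at least two modelled
species (`filter_groups_min_species` enforces this rule on input data).
Hyperpriors are `mu ~ Normal(0, 10)` and `sigma ~ Uniform(0, 5)`. The
second normal argument is interpreted as a **variance** (sd ≈ 3.16 on the
logit scale, weakly informative); it is configurable via
`PriorConfig.mu_var` for sensitivity analysis, and `prior_sensitivity()`
automates refitting under a grid of prior settings.

### Unknown species richness

For richness estimation the detection array is padded to `M` species rows
(all-zero pseudo-species) with inclusion indicators
`a_k ~ Bernoulli(Omega)`, `Omega ~ Uniform(0, 1)` and
`z_ik ~ Bernoulli(psi_ik * a_k)`. Posterior richness is `N = sum(a_k)`.
`check_augmentation_sufficiency` declares `M` adequate when
`P(N >= M-1) < 0.01`; this operationalizes "M sits in the far right tail of
the posterior of N" with a concrete threshold. Augmentation cannot be
combined with group-level hyperparameters (pseudo-species have no group).

## Sampler

Metropolis-within-Gibbs with explicit latent states, chosen over a
marginalized HMC formulation because every conditional has a closed form
that can be tested against enumeration oracles:

* `w | z, y` and `z | w` are exact Bernoulli conditionals (e.g.
  `P(z=1 | all w=0) = psi * prod_j(1-theta_j) / (psi * prod_j(1-theta_j) + 1-psi)`).
* For pseudo-species the sweep is partially collapsed: `a_k` is drawn with
  (z, w) marginalized out through the all-zero unit likelihood, then `z`
  and `w` are drawn compatibly; `Omega` is a conjugate
  `Beta(1 + sum a, 1 + M - sum a)` draw.
* Species coefficients use per-parameter adaptive Gaussian random walks
  against the Bernoulli complete-data likelihood times the hierarchical
  normal prior. Step sizes adapt toward 0.44 acceptance in batches of 50
  iterations during burn-in only and are frozen afterwards, so the
  stationary distribution is untouched. Non-finite proposal densities are
  rejected, never fatal. Coefficients of excluded pseudo-species
  (`a_k = 0`) have no likelihood term and are refreshed exactly from the
  community prior.
* Community means are conjugate normal Gibbs draws; community sds use a
  log-scale random walk with the uniform prior enforced by rejection.
  Additionally, each sd gets an ancillarity–sufficiency interweaving move:
  holding the standardized residuals `u_k = (c_k - mu)/sigma` fixed, a
  log-scale proposal rescales sigma and every coefficient of the family
  jointly and is accepted against the complete-data likelihood (plus the
  log-scale Jacobian). This crosses the `sigma -> 0` funnel that centered
  updates traverse only slowly; without it the capture-level sd could trap
  a chain near zero for thousands of iterations.
* When a categorical detection covariate is present, the intercept and the
  level effects are aliased: only `lp_k + mean_l beta2_k[l]` is
  likelihood-identified, a consequence of fitting all levels without a
  corner constraint. Two exact conjugate recentring moves sample along this
  ridge — per species between `lp_k` and `beta2_k[·]`, and at the community
  level between `mu_lp` and `mu_beta2` — using the normal priors alone,
  since the likelihood is invariant there. Identified summaries (detection
  at reference settings, level contrasts) then mix well even though raw
  `mu_lp` and `mu_beta2` are individually diffuse.

Initialization: `z` and `w` at their data-forced values (1 wherever a
detection occurred), coefficients at 0, sigmas at 1, and
`Omega = (K_obs + 1)/(M + 2)`. One master seed expands into per-chain
`SeedSequence` streams; identical data, spec, config and seed reproduce
bit-identical draws. Draw storage is `(n_iterations - burn_in)/thin` per
chain; defaults follow the conventional heavy-duty setting for this model
class (3 chains × 50,000 iterations, 10,000 burn-in, thinning 10), and all
package tests use much shorter, explicitly configured runs.

## Assessment

All criteria share one likelihood unit: the site × species **marginal**
likelihood with (z, w) summed out,

    P(y_i.k) = psi * prod_j [theta * prod_r p^y (1-p)^(1-y)
                             + (1-theta) * 1(sample j all zero)]
               + (1-psi) * 1(unit all zero),

computed in log space with probabilities clamped to
`[1e-300, 1 - 1e-16]`; masked (unobserved) cells drop out of every product,
and a sample with no observed replicates marginalizes to 1.

* **Deviance residuals**: per unit and draw,
  `sign(obs - E) * sqrt(-2 log P)`, with `E` the expected detections
  `sum psi*theta*p` over the unit's observed cells; reported as the
  posterior mean and plotted by species, site and covariate.
* **Bayesian p-value**: for each retained draw, a full replicate dataset is
  simulated from that draw's parameters on the same design and
  `P(D_rep > D_obs)` is the fraction of draws whose replicate deviance
  exceeds the observed one. Values near 0.5 indicate adequate fit; outside
  (0.05, 0.95), misfit.
* **WAIC** `= -2 (lppd - p_WAIC)` with `lppd` via log-sum-exp over draws and
  `p_WAIC` the per-unit posterior variance of the log likelihood (ddof 1).
* **CPO criterion**: `CPO_unit` is the harmonic mean over draws of the unit
  likelihood; the default criterion is `sum_units 1/CPO_unit` (magnitudes
  in the millions on realistic surveys), with `-sum log CPO` available via
  a flag. Per-unit terms are clamped at `exp(700)` so the criterion stays
  finite, with a warning naming the number of clamped units.
* **Cross-validation**: sites are the fold unit (they are the exchangeable
  top-level sampling unit), k defaults to 5. Each fold refits the model
  without the held-out sites; held-out cells are predicted unconditionally
  as the posterior mean of `psi*theta*p` (a new site contributes no
  latent-state information). Species undetected in a training split are
  predicted through fresh coefficient draws from the community posteriors.
  Brier and log scores are **summed** over held-out cells.
* **Model comparison** ranks models per criterion (lower is better for all
  four) and takes the majority winner as consensus; ties and split verdicts
  are reported, never silently broken.
* **Convergence**: Gelman–Rubin
  `R = sqrt(((n-1)/n W + B/n) / W)` from ≥2 chains; `W = 0` is an error.
* **HDI**: the shortest contiguous window of the sorted draws containing
  `ceil(mass * n)` draws, ties resolved toward the lowest window. A slope
  is flagged significant when its 95% HDI excludes zero.

## Simulator

`SimulationScenario` runs the generative chain forward for a community of
`K_true` species and reports both the observed survey (species with at
least one detection) and a complete truth record (all parameters, latent
states, the full detection array, undetected species, seed and a scenario
hash for exact re-simulation). Defaults emulate a small coastal survey:
8 sites × 3 bottles × 5 amplicon assays; water depth ~ Uniform(5, 60) m on
occupancy; sequencing depth ~ LogNormal(meanlog 15.9, sdlog 0.29) reads
(≈ 8.1 M ± 30%) on detection; amplicon identity as a 5-level categorical,
one level per technical replicate. Community defaults put mean occupancy
near 0.29, capture near 0.96 and detection near 0.14 with moderate
between-species spread — the regime coastal eDNA surveys report — and a
negative depth effect on occupancy. `K_true = 30` keeps the default
desk-scale.

What the simulator does **not** emulate: read counts, PCR chemistry and
stochasticity below the replicate level, taxonomy-assignment error (hence
false positives), spatial or temporal correlation between sites, and
abundance. Tests passing on these simulations therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to the violations real surveys add.

`design_sweep` tabulates the detected fraction of the community (and
optionally the richness-interval width from augmented refits) over grids of
sites/samples/replicates, the quantity a survey designer trades against
cost.

## Numerical choices

* Log-space likelihoods throughout via `log(sigmoid)`; probability clamps
  `[1e-300, 1 - 1e-16]` keep admissible states away from `-inf` during
  MCMC.
* Community sds are floored at `1e-8` in density evaluations; proposals
  outside `(1e-8, sigma_upper)` are rejected.
* Random-walk steps start at 1.0 (coefficients) and 0.5 (hyper sds), with
  adaptation gain `min(0.5, 2/sqrt(batch))`.
* Missing cells are first-class: the detection-table reader can treat
  absent rows as `y = 0` or as unobserved (masked), and every likelihood,
  residual and score skips masked cells.

## Test and acceptance problem sizes

The test suite and `scripts/acceptance.py` run seeded studies sized for a
single CPU: hyperparameter recovery uses 20 species × 50 sites × 3 samples
× 4 replicates with 3 chains × 5,000 iterations (3–5 replicate surveys);
richness recovery uses a 30-species community thinned to ~20–25 observed,
augmented to M = 60, with 3 chains × 3,000 iterations; model selection and
calibration use smaller surveys with 2 × 1,500-iteration chains.
Proportional thresholds accompany the scaled replicate counts (e.g. HDI
coverage in ≥ 4 of 5 surveys).

## Known limitations

* With small communities (tens of species), the posterior of richness `N`
  is right-skewed and its upper tail approaches the augmentation bound more
  than 1% of the time at `M = 2 K_true`; `check_augmentation_sufficiency`
  then correctly reports `M` as insufficient, and the practical remedy is a
  larger `M`. Point estimates of `N` in this regime are upward-biased even
  when the 95% HDI covers the truth.
* No false-positive observation level: contamination or misassigned reads
  violate the model.
* Single-season (static) occupancy only; no colonization/extinction
  dynamics.
* Species permutation equivariance holds in distribution, not bit-for-bit:
  the sampler's vectorized RNG streams are positional, so relabeling
  species changes which random numbers each receives.
* Detection covariates support at most one categorical covariate per model.
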