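"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from triocc import (
    McmcConfig,
    SimulationScenario,
    run_mcmc,
    simulate_dataset,
)


def enumerate_marginal_loglik(y, mask, psi, theta, p):
    """Brute-force marginal likelihood of a full dataset by exhaustive
    enumeration over every latent (z, w) configuration.

    y : (I, J, R, K); psi : (I, K); theta : (I, J, K); p : (I, J, R, K).
    Independent of the package's log-space recursion; feasible for
    I*J*R*K <= ~16 only.
    """
    I, J, R, K = y.shape
    total = 0.0
    for i in range(I):
        for k in range(K):
            unit = 0.0
            for z in (0, 1):
                pz = psi[i, k] if z else 1.0 - psi[i, k]
                site = 1.0
                for j in range(J):
                    sample = 0.0
                    for w in (0, 1):
                        th = theta[i, j, k]
                        pw = (th if w else 1.0 - th) if z else (0.0 if w else 1.0)
                        lik = 1.0
                        for r in range(R):
                            if not mask[i, j, r, k]:
                                continue
                            pr = p[i, j, r, k] if w else 0.0
                            lik *= pr if y[i, j, r, k] else 1.0 - pr
                        sample += pw * lik
                    site *= sample
                unit += pz * site
            total += np.log(unit)
    return total


def random_tiny_instance(rng, max_cells=16, allow_mask=True):
    """A random small DetectionArray + probabilities for oracle comparisons."""
    while True:
        I, J, R, K = (int(rng.integers(1, 4)) for _ in range(4))
        if I * J * R * K <= max_cells:
            break
    psi = rng.uniform(0.05, 0.95, (I, K))
    theta = rng.uniform(0.05, 0.95, (I, J, K))
    p = rng.uniform(0.05, 0.95, (I, J, R, K))
    mask = np.ones((I, J, R, K), dtype=bool)
    if allow_mask and rng.random() < 0.5:
        mask &= rng.random((I, J, R, K)) < 0.85
        if not mask.any():
            mask[0, 0, 0, 0] = True
    y = ((rng.random((I, J, R, K)) < 0.5) & mask).astype(np.int8)
    return y, mask, psi, theta, p


@pytest.fixture(scope="session")
def small_scenario():
    return SimulationScenario(
        I=12, J=2, R=3, K_true=10,
        mu_lpsi=0.0, sigma_lpsi=0.7, mu_ltheta=1.5, sigma_ltheta=0.4,
        mu_lp=0.0, sigma_lp=0.4, mu_beta3=1.0, sigma_beta3=0.3,
        mu_beta1=0.3, sigma_beta1=0.2, include_amplicon=False,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_fit(small_dataset, small_scenario):
    """A short but real fit shared by assessment/summary tests."""
    data, cov, truth = small_dataset
    spec = small_scenario.model_spec()
    cfg = McmcConfig(n_chains=2, n_iterations=1200, burn_in=400, thin=4, seed=7)
    return run_mcmc(data, cov, spec, cfg), data, cov, spec
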