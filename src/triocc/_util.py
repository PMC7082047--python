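"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit  # noqa: F401  (re-exported)
from scipy.special import log_expit

# Probabilities are clamped away from {0, 1} before any log so that a
# Metropolis sweep never produces -inf for an admissible state.
PROB_FLOOR = 1e-300
PROB_CEIL = 1.0 - 1e-16


def clamp_prob(p):
    """Clip probabilities into [PROB_FLOOR, PROB_CEIL]."""
    return np.clip(p, PROB_FLOOR, PROB_CEIL)


def inv_logit(eta):
    """Inverse logit, clamped so the result is strictly inside (0, 1)."""
    return clamp_prob(expit(eta))


def logit(p):
    return _logit(p)


def log_inv_logit(eta):
    """log(sigmoid(eta)), computed without underflow."""
    return log_expit(eta)


def bernoulli_loglik(y, eta):
    """Pointwise Bernoulli log-likelihood with logit-scale parameter eta."""
    return np.where(y, log_expit(eta), log_expit(-eta))


def rng_from_seed(seed):
    """Normalize None/int/Generator/SeedSequence into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n):
    """Derive n child SeedSequences deterministically from a master seed."""
    return np.random.SeedSequence(seed).spawn(n)
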