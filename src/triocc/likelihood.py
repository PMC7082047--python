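"""Link functions and the latent-state-marginalized likelihood.

The model couples three Bernoulli levels,

    z_ik   ~ Bernoulli(psi_ik)            site occupancy
    w_ijk  ~ Bernoulli(theta_ijk * z_ik)  capture in a biological sample
    y_ijrk ~ Bernoulli(p_ijrk * w_ijk)    detection in a technical replicate

with logit links

    logit(psi_ik)  = lpsi_k  + beta3_k * x3_i
    logit(theta_ijk) = ltheta_k (+ sample-level covariate terms)
    logit(p_ijrk)  = lp_k + beta1_k * x1_ijr + beta2_k[level(x2_ijr)].

Everything downstream (WAIC, CPO, cross-validation scores, deviance
residuals, the augmented inclusion update) consumes the *marginal* likelihood
of one site x species unit with (z, w) summed out:

    P(y_i.k) = psi * prod_j [ theta * prod_r p^y (1-p)^(1-y)
                              + (1-theta) * 1(all y_ij. = 0) ]
               + (1-psi) * 1(all y_i.. = 0)

computed in log space.  Masked (unobserved) cells drop out of all products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import inv_logit, log_inv_logit
from .data import (
    CovariateSet,
    DataValidationError,
    DetectionArray,
    ModelSpec,
    SpeciesParams,
)

NEG_INF = -np.inf


# --------------------------------------------------------------------------
# design: covariates resolved into dense arrays for a given spec
# --------------------------------------------------------------------------


@dataclass
class Design:
    """Covariate arrays resolved against a ModelSpec.

    x_psi   : (I, C_psi) site covariates on occupancy
    x_theta : (I, J, C_theta) sample covariates on capture
    x_p     : (I, J, R, C_p) continuous replicate covariates on detection
    codes   : (I, J, R) integer levels of the categorical detection
              covariate, or None
    """

    x_psi: np.ndarray
    x_theta: np.ndarray
    x_p: np.ndarray
    codes: np.ndarray | None
    n_levels: int
    level_labels: list[str]
    categorical_name: str | None


def build_design(data_shape, cov: CovariateSet, spec: ModelSpec) -> Design:
    I, J, R, _ = data_shape
    x_psi = (
        np.stack([cov.site_continuous[n] for n in spec.psi_covariates], axis=-1)
        if spec.psi_covariates
        else np.zeros((I, 0))
    )
    x_theta = (
        np.stack([cov.sample_continuous[n] for n in spec.theta_covariates], axis=-1)
        if spec.theta_covariates
        else np.zeros((I, J, 0))
    )
    cont_p = [n for n in spec.p_covariates if cov.level_of(n) == "replicate"]
    cat_p = [n for n in spec.p_covariates if cov.level_of(n) == "replicate_categorical"]
    x_p = (
        np.stack([cov.replicate_continuous[n] for n in cont_p], axis=-1)
        if cont_p
        else np.zeros((I, J, R, 0))
    )
    if cat_p:
        cc = cov.replicate_categorical[cat_p[0]]
        codes, n_levels, level_labels, cat_name = cc.codes, cc.n_levels, cc.levels, cat_p[0]
    else:
        codes, n_levels, level_labels, cat_name = None, 0, [], None
    for arr, expected in ((x_psi, (I,)), (x_theta, (I, J)), (x_p, (I, J, R))):
        if arr.shape[: len(expected)] != expected:
            raise DataValidationError(
                f"covariate array shape {arr.shape} incompatible with data shape {data_shape}"
            )
    return Design(x_psi, x_theta, x_p, codes, n_levels, level_labels, cat_name)


# --------------------------------------------------------------------------
# linear predictors and probabilities (vectorized over all indices)
# --------------------------------------------------------------------------


def psi_eta(params: SpeciesParams, design: Design):
    """Logit-scale occupancy, shape (I, K)."""
    eta = np.broadcast_to(params.lpsi, (design.x_psi.shape[0], params.n_species)).copy()
    if design.x_psi.shape[-1]:
        if params.beta3 is None:
            raise DataValidationError("spec includes occupancy covariates but beta3 is missing")
        eta += design.x_psi @ params.beta3.T
    return eta


def theta_eta(params: SpeciesParams, design: Design):
    """Logit-scale capture, shape (I, J, K)."""
    I, J = design.x_theta.shape[:2]
    eta = np.broadcast_to(params.ltheta, (I, J, params.n_species)).copy()
    if design.x_theta.shape[-1]:
        if params.btheta is None:
            raise DataValidationError("spec includes capture covariates but btheta is missing")
        eta += np.einsum("ijc,kc->ijk", design.x_theta, params.btheta)
    return eta


def p_eta(params: SpeciesParams, design: Design):
    """Logit-scale detection, shape (I, J, R, K)."""
    I, J, R = design.x_p.shape[:3]
    eta = np.broadcast_to(params.lp, (I, J, R, params.n_species)).copy()
    if design.x_p.shape[-1]:
        if params.beta1 is None:
            raise DataValidationError("spec includes detection covariates but beta1 is missing")
        eta += np.einsum("ijrc,kc->ijrk", design.x_p, params.beta1)
    if design.codes is not None:
        if params.beta2 is None:
            raise DataValidationError("spec includes a categorical covariate but beta2 is missing")
        if params.beta2.shape[1] != design.n_levels:
            raise DataValidationError("beta2 level count does not match the categorical covariate")
        eta += np.moveaxis(params.beta2[:, design.codes], 0, -1)
    return eta


def psi_matrix(params, cov, spec, data_shape):
    return inv_logit(psi_eta(params, build_design(data_shape, cov, spec)))


def theta_matrix(params, cov, spec, data_shape):
    return inv_logit(theta_eta(params, build_design(data_shape, cov, spec)))


def p_matrix(params, cov, spec, data_shape):
    return inv_logit(p_eta(params, build_design(data_shape, cov, spec)))


def _check_index(name, idx, n):
    if not 0 <= idx < n:
        raise IndexError(f"{name} index {idx} out of range [0, {n})")


def psi_prob(params, cov, spec, data_shape, site, species):
    """Occupancy probability for one site x species; strictly in (0, 1)."""
    _check_index("site", site, data_shape[0])
    _check_index("species", species, params.n_species)
    return float(psi_matrix(params, cov, spec, data_shape)[site, species])

def theta_prob(params, cov, spec, data_shape, site, sample, species):
    """Capture probability for one site x sample x species."""
    _check_index("site", site, data_shape[0])
    _check_index("sample", sample, data_shape[1])
    _check_index("species", species, params.n_species)
    return float(theta_matrix(params, cov, spec, data_shape)[site, sample, species])

def p_prob(params, cov, spec, data_shape, site, sample, replicate, species):
    """Detection probability for one replicate cell (computable for masked
    cells too; those are used only for prediction)."""
    _check_index("site", site, data_shape[0])
    _check_index("sample", sample, data_shape[1])
    _check_index("replicate", replicate, data_shape[2])
    _check_index("species", species, params.n_species)
    return float(p_matrix(params, cov, spec, data_shape)[site, sample, replicate, species])


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------


def _logaddexp_branch(log_a, log_b, take_b):
    """logaddexp(log_a, log_b) where take_b, else log_a."""
    return np.where(take_b, np.logaddexp(log_a, log_b), log_a)


def unit_loglik_matrix(y, mask, eta_psi, eta_theta, eta_p):
    """Marginal log-likelihood of every (site, species) unit, shape (I, K).

    All inputs are logit-scale arrays: eta_psi (I, K), eta_theta (I, J, K),
    eta_p (I, J, R, K).  Latent z and w are summed out analytically.
    """
    mask = np.broadcast_to(mask, y.shape)
    if (y.astype(bool) & ~mask).any():
        raise DataValidationError("detection recorded in a masked-out cell")
    yb = y.astype(bool)
    # per-cell detection log-likelihood, masked cells contribute 0
    cell = np.where(mask, np.where(yb, log_inv_logit(eta_p), log_inv_logit(-eta_p)), 0.0)
    s = cell.sum(axis=2)  # (I, J, K): sum over replicates
    allzero_j = ~(yb & mask).any(axis=2)  # (I, J, K)
    has_obs_j = mask.any(axis=2)
    logt1 = log_inv_logit(eta_theta)
    logt0 = log_inv_logit(-eta_theta)
    # f_j = theta * prod_r Bern + (1-theta) * 1(no detection in sample j)
    logf = _logaddexp_branch(logt1 + s, logt0, allzero_j)
    logf = np.where(has_obs_j, logf, 0.0)  # unobserved samples marginalize to 1
    S = logf.sum(axis=1)  # (I, K)
    allzero_unit = allzero_j.all(axis=1)
    logpsi1 = log_inv_logit(eta_psi)
    logpsi0 = log_inv_logit(-eta_psi)
    return _logaddexp_branch(logpsi1 + S, logpsi0, allzero_unit)


def marginal_unit_loglik(y_slice, psi, theta_row, p_matrix, mask=None):
    """Marginal log-likelihood of one site x species unit.

    y_slice : (J, R) detections for the unit; theta_row : (J,) capture
    probabilities; p_matrix : (J, R) detection probabilities; mask marks
    observed cells.  Probabilities must lie strictly in (0, 1) after the
    package-wide clamping (an impossible configuration -- a detection scored
    against p = 0 -- still yields -inf).
    """
    y2 = np.atleast_2d(np.asarray(y_slice, dtype=np.int8))  # (J, R)
    y4 = y2.reshape(1, y2.shape[0], y2.shape[1], 1)
    mask = (
        np.ones_like(y4, dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool).reshape(y4.shape)
    )
    from ._util import logit as _lg

    eta_psi = _lg(np.asarray([[psi]], dtype=float))
    eta_theta = _lg(np.broadcast_to(np.asarray(theta_row, dtype=float), (y2.shape[0],)).reshape(1, -1, 1))
    eta_p = _lg(np.broadcast_to(np.asarray(p_matrix, dtype=float), y2.shape).reshape(y4.shape))
    y_slice = y4
    return float(unit_loglik_matrix(y_slice, mask, eta_psi, eta_theta, eta_p)[0, 0])


def total_marginal_loglik(data: DetectionArray, params: SpeciesParams, cov: CovariateSet,
                          spec: ModelSpec):
    """Sum of marginal unit log-likelihoods over all sites and species."""
    if params.n_species != data.n_species:
        raise DataValidationError(
            f"parameter set covers {params.n_species} species but data has {data.n_species}"
        )
    design = build_design(data.shape, cov, spec)
    mat = unit_loglik_matrix(
        data.y, data.observed_mask, psi_eta(params, design),
        theta_eta(params, design), p_eta(params, design),
    )
    return float(mat.sum())


def expected_detections_matrix(eta_psi, eta_theta, eta_p, mask):
    """E[number of detections] per unit = sum over cells of psi*theta*p."""
    prod = (
        inv_logit(eta_psi)[:, None, None, :]
        * inv_logit(eta_theta)[:, :, None, :]
        * inv_logit(eta_p)
    )
    return (prod * mask).sum(axis=(1, 2))


__all__ = [
    "Design",
    "build_design",
    "psi_eta",
    "theta_eta",
    "p_eta",
    "psi_matrix",
    "theta_matrix",
    "p_matrix",
    "psi_prob",
    "theta_prob",
    "p_prob",
    "unit_loglik_matrix",
    "marginal_unit_loglik",
    "total_marginal_loglik",
    "expected_detections_matrix",
]
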