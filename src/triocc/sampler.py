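"""Metropolis-within-Gibbs sampler for the three-level occupancy model.

The sampler mirrors the explicit latent-state (BUGS-style) formulation:

* latent capture states ``w`` and occupancy states ``z`` are drawn from
  their exact full conditionals (Gibbs);
* species-level logit-scale coefficients use adaptive Gaussian random-walk
  Metropolis steps against the Bernoulli complete-data likelihood times the
  hierarchical normal prior;
* community means ``mu`` are conjugate normal Gibbs draws; community sds
  ``sigma`` use a random-walk on log(sigma) under the Uniform(0, upper)
  prior;
* for unknown richness the array is padded to M species rows and the
  inclusion indicators ``a_k`` are drawn from a partially collapsed
  conditional with (z, w) marginalized out, followed by compatible draws of
  z and w; ``Omega`` is a conjugate Beta draw.

Step sizes adapt toward a 0.44 acceptance rate during burn-in only and are
frozen afterwards, preserving the stationary distribution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import log_expit

from .data import (
    CovariateSet,
    DataValidationError,
    DetectionArray,
    ModelSpec,
    PriorConfig,
)
from .likelihood import Design, build_design

_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run settings (defaults follow common practice for this model
    class: 3 chains of 50,000 iterations, 10,000 burn-in, thinning 10)."""

    n_chains: int = 3
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int | None = None
    target_accept: float = 0.44
    adapt_interval: int = 50

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iterations:
            raise DataValidationError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise DataValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise DataValidationError("need at least one chain")

    @property
    def n_saved(self):
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned draws indexed by (chain, saved iteration).

    ``draws`` maps parameter name -> array of shape (n_chains, n_saved, ...):
    species coefficients (lpsi, ltheta, lp, beta1, beta2, beta3, btheta),
    community hyperparameters (mu_*, sigma_*), latent states z and w, and --
    for augmented fits -- a, N = sum(a) and omega.
    """

    draws: dict
    species_labels: list
    n_observed_species: int
    spec: ModelSpec
    config: McmcConfig
    group_labels: list | None = None
    acceptance: dict = field(default_factory=dict)
    data_fingerprint: str = ""

    @property
    def n_chains(self):
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_saved(self):
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_total_draws(self):
        return self.n_chains * self.n_saved

    def stacked(self, name):
        """All chains concatenated: shape (n_chains * n_saved, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def parameter_names(self):
        return list(self.draws)

    def community_parameter_names(self):
        return [n for n in self.draws if n.startswith(("mu_", "sigma_"))] + (
            ["omega"] if "omega" in self.draws else []
        )

    def to_long_dataframe(self, parameters=None, include_latent=False):
        """Long-format export: chain, iteration, parameter, value."""
        import pandas as pd

        rows = []
        names = parameters if parameters is not None else list(self.draws)
        for name in names:
            if not include_latent and name in ("z", "w"):
                continue
            arr = self.draws[name]
            C, S = arr.shape[:2]
            flat = arr.reshape(C, S, -1)
            for idx in range(flat.shape[2]):
                sub = np.unravel_index(idx, arr.shape[2:]) if arr.ndim > 2 else ()
                pname = name + "".join(f"[{i}]" for i in sub)
                for c in range(C):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(S),
                                "parameter": pname,
                                "value": flat[c, :, idx],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, path):
        """Compact cache (NumPy .npz + JSON metadata) for reuse."""
        import json

        meta = {
            "species_labels": self.species_labels,
            "n_observed_species": self.n_observed_species,
            "group_labels": self.group_labels,
            "acceptance": self.acceptance,
            "data_fingerprint": self.data_fingerprint,
            "config": asdict(self.config),
            "spec": _spec_to_dict(self.spec),
        }
        np.savez_compressed(path, _meta=np.array(json.dumps(meta)), **self.draws)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            draws = {k: f[k] for k in f.files if k != "_meta"}
        return cls(
            draws=draws,
            species_labels=meta["species_labels"],
            n_observed_species=meta["n_observed_species"],
            spec=_spec_from_dict(meta["spec"]),
            config=McmcConfig(**meta["config"]),
            group_labels=meta["group_labels"],
            acceptance=meta["acceptance"],
            data_fingerprint=meta["data_fingerprint"],
        )


def _spec_to_dict(spec: ModelSpec):
    return {
        "psi_covariates": list(spec.psi_covariates),
        "theta_covariates": list(spec.theta_covariates),
        "p_covariates": list(spec.p_covariates),
        "augmentation_M": spec.augmentation_M,
        "group_map": spec.group_map,
        "priors": asdict(spec.priors),
        "label": spec.label,
    }


def _spec_from_dict(d):
    d = dict(d)
    d["priors"] = PriorConfig(**d["priors"])
    return ModelSpec(**d)


# --------------------------------------------------------------------------
# closed-form full conditionals (also used directly by tests)
# --------------------------------------------------------------------------


def z_full_conditional_prob(w_row, psi, theta_row):
    """P(z = 1 | w, psi, theta) for one site x species unit.

    Equals 1 whenever any capture occurred; otherwise
    psi * prod_j (1 - theta_j) / [psi * prod_j (1 - theta_j) + (1 - psi)].
    """
    w_row = np.asarray(w_row, dtype=bool)
    theta_row = np.broadcast_to(np.asarray(theta_row, dtype=float), w_row.shape)
    if w_row.any():
        return 1.0
    num = psi * np.prod(1.0 - theta_row)
    return num / (num + (1.0 - psi))


def w_full_conditional_prob(y_row, z, theta, p_row):
    """P(w = 1 | y, z, theta, p) for one sample x species unit.

    0 when the site is unoccupied; 1 when any replicate detected the species
    (a detection with z = 0 is an impossible state and raises); otherwise
    theta * prod_r (1 - p_r) / [theta * prod_r (1 - p_r) + (1 - theta)].
    """
    y_row = np.asarray(y_row, dtype=bool)
    p_row = np.broadcast_to(np.asarray(p_row, dtype=float), y_row.shape)
    if not z:
        if y_row.any():
            raise DataValidationError("impossible state: detection recorded while z = 0")
        return 0.0
    if y_row.any():
        return 1.0
    num = theta * np.prod(1.0 - p_row)
    return num / (num + (1.0 - theta))


def a_full_conditional_prob(omega, psi_by_site, theta, p, mask=None):
    """P(a_k = 1 | all-zero data) for one augmented pseudo-species.

    psi_by_site : (I,) occupancy probabilities; theta : (I, J); p : (I, J, R).
    The detection history is all-zero by construction, so the inner (z, w)
    levels marginalize to the all-zero unit likelihood
    prod_i [psi_i * prod_j (theta_ij * prod_r (1 - p_ijr) + 1 - theta_ij)
            + (1 - psi_i)].
    """
    psi_by_site = np.atleast_1d(np.asarray(psi_by_site, dtype=float))
    I = psi_by_site.shape[0]
    theta = np.asarray(theta, dtype=float).reshape(I, -1)
    p = np.asarray(p, dtype=float).reshape(I, theta.shape[1], -1)
    if mask is None:
        mask = np.ones_like(p, dtype=bool)
    s0 = (np.log1p(-p) * mask).sum(axis=2)
    f0 = theta * np.exp(s0) + (1.0 - theta)
    unit = psi_by_site * f0.prod(axis=1) + (1.0 - psi_by_site)
    L0 = float(np.prod(unit))
    return omega * L0 / (omega * L0 + (1.0 - omega))


# --------------------------------------------------------------------------
# chain state
# --------------------------------------------------------------------------


def _log_bern(b, eta):
    return np.where(b, log_expit(eta), log_expit(-eta))


class ChainState:
    """Mutable state of one MCMC chain with its update sweeps.

    Exposed for testing: the sweeps (`update_latent_states`,
    `update_species_coefficients`, `update_hyperparameters`,
    `update_augmentation`) can be invoked individually with parts of the
    state pinned.
    """

    def __init__(self, data: DetectionArray, design: Design, spec: ModelSpec,
                 group_idx, n_groups, rng):
        self.rng = rng
        self.spec = spec
        self.design = design
        self.prior = spec.priors
        self.M = spec.augmentation_M
        I, J, R, K = data.shape
        self.I, self.J, self.R, self.K = I, J, R, K
        self.K_obs = data.n_observed_species
        self.yb = data.y.astype(bool)
        self.mask4 = np.broadcast_to(data.observed_mask, data.y.shape)
        self.anyY_jk = (self.yb & self.mask4).any(axis=2)  # (I, J, K)
        self.anyY_ik = self.anyY_jk.any(axis=1)  # (I, K)
        self.has_obs_j = self.mask4.any(axis=2)  # (I, J, K)
        self.group_idx = np.asarray(group_idx, dtype=np.intp)
        self.n_groups = n_groups

        c_psi = design.x_psi.shape[-1]
        c_theta = design.x_theta.shape[-1]
        c_p = design.x_p.shape[-1]
        L = design.n_levels
        self.families = {"lpsi": 1, "ltheta": 1, "lp": 1}
        self.coef = {
            "lpsi": np.zeros(K),
            "ltheta": np.zeros(K),
            "lp": np.zeros(K),
        }
        if c_psi:
            self.coef["beta3"] = np.zeros((K, c_psi))
            self.families["beta3"] = c_psi
        if c_theta:
            self.coef["btheta"] = np.zeros((K, c_theta))
            self.families["btheta"] = c_theta
        if c_p:
            self.coef["beta1"] = np.zeros((K, c_p))
            self.families["beta1"] = c_p
        if L:
            self.coef["beta2"] = np.zeros((K, L))
            self.families["beta2"] = 1  # one (mu, sigma) shared across levels
        self.n_levels = L

        self.mu = {f: np.zeros((n_groups, nc)) for f, nc in self.families.items()}
        self.sigma = {f: np.ones((n_groups, nc)) for f, nc in self.families.items()}

        # latent states initialized at their data-forced values
        self.z = self.anyY_ik.astype(np.int8)
        self.w = self.anyY_jk.astype(np.int8)
        self.a = np.ones(K, dtype=np.int8)
        self.omega = None
        if self.M:
            self.omega = (self.K_obs + 1) / (self.M + 2)
            self.a[self.K_obs:] = self.rng.random(K - self.K_obs) < self.omega

        # one random-walk block per family column / categorical level
        self.blocks = []
        for fam in self.coef:
            ncols = 1 if self.coef[fam].ndim == 1 else self.coef[fam].shape[1]
            for c in range(ncols):
                self.blocks.append((fam, c))
        self.step = {b: np.full(K, 1.0) for b in self.blocks}
        self.acc = {b: np.zeros(K) for b in self.blocks}
        self.att = 0
        self.hyper_step = {f: np.full((n_groups, nc), 0.5) for f, nc in self.families.items()}
        self.hyper_acc = {f: np.zeros((n_groups, nc)) for f, nc in self.families.items()}
        self.nc_step = {f: np.full((n_groups, nc), 0.5) for f, nc in self.families.items()}
        self.nc_acc = {f: np.zeros((n_groups, nc)) for f, nc in self.families.items()}
        self.hyper_att = 0

    # -- linear predictors -------------------------------------------------

    def _eta_psi(self, lpsi=None, beta3=None):
        lpsi = self.coef["lpsi"] if lpsi is None else lpsi
        eta = np.broadcast_to(lpsi, (self.I, self.K)).copy()
        if "beta3" in self.coef:
            b3 = self.coef["beta3"] if beta3 is None else beta3
            eta += self.design.x_psi @ b3.T
        return eta

    def _eta_theta(self, ltheta=None, btheta=None):
        lt = self.coef["ltheta"] if ltheta is None else ltheta
        eta = np.broadcast_to(lt, (self.I, self.J, self.K)).copy()
        if "btheta" in self.coef:
            bt = self.coef["btheta"] if btheta is None else btheta
            eta += np.einsum("ijc,kc->ijk", self.design.x_theta, bt)
        return eta

    def _eta_p(self, lp=None, beta1=None, beta2=None):
        lp_ = self.coef["lp"] if lp is None else lp
        eta = np.broadcast_to(lp_, (self.I, self.J, self.R, self.K)).copy()
        if "beta1" in self.coef:
            b1 = self.coef["beta1"] if beta1 is None else beta1
            eta += np.einsum("ijrc,kc->ijrk", self.design.x_p, b1)
        if "beta2" in self.coef:
            b2 = self.coef["beta2"] if beta2 is None else beta2
            eta += np.moveaxis(b2[:, self.design.codes], 0, -1)
        return eta

    # -- complete-data log-likelihoods per species -------------------------

    def _ll_psi(self, lpsi=None, beta3=None):
        eta = self._eta_psi(lpsi, beta3)
        zb = self.z.astype(bool)
        ll = _log_bern(zb, eta)
        if self.M:  # a_k = 0 species carry no occupancy likelihood
            ll = ll * self.a.astype(bool)[None, :]
        return ll.sum(axis=0)

    def _ll_theta(self, ltheta=None, btheta=None):
        eta = self._eta_theta(ltheta, btheta)
        wb = self.w.astype(bool)
        ll = np.where(self.z.astype(bool)[:, None, :], _log_bern(wb, eta), 0.0)
        return ll.sum(axis=(0, 1))

    def _ll_p(self, lp=None, beta1=None, beta2=None):
        eta = self._eta_p(lp, beta1, beta2)
        use = self.mask4 & self.w.astype(bool)[:, :, None, :]
        ll = np.where(use, _log_bern(self.yb, eta), 0.0)
        return ll.sum(axis=(0, 1, 2))

    # -- latent state sweep ------------------------------------------------

    def update_latent_states(self):
        rng = self.rng
        eta_t = self._eta_theta()
        eta_z = self._eta_psi()
        logt1, logt0 = log_expit(eta_t), log_expit(-eta_t)
        logpsi1, logpsi0 = log_expit(eta_z), log_expit(-eta_z)
        s0 = (log_expit(-self._eta_p()) * self.mask4).sum(axis=2)  # (I, J, K)
        logf0 = np.logaddexp(logt1 + s0, logt0)
        logf0 = np.where(self.has_obs_j, logf0, 0.0)

        ko = slice(0, self.K_obs)
        # w | z, y
        pw = np.exp(logt1[..., ko] + s0[..., ko] - logf0[..., ko])
        w_o = rng.random(pw.shape) < pw
        w_o = np.where(self.anyY_jk[..., ko], True, w_o)
        w_o &= self.z.astype(bool)[:, ko][:, None, :]
        # z | w
        sw = _log_bern(w_o, eta_t[..., ko]).sum(axis=1)  # (I, K_obs)
        lnum = logpsi1[:, ko] + sw
        pz = np.exp(lnum - np.logaddexp(lnum, logpsi0[:, ko]))
        z_o = rng.random(pz.shape) < pz
        z_o |= w_o.any(axis=1)
        w_o &= z_o[:, None, :]
        self.z[:, ko] = z_o
        self.w[..., ko] = w_o

        if self.M:
            self.update_augmentation(s0=s0, logf0=logf0, logt1=logt1,
                                     logpsi1=logpsi1, logpsi0=logpsi0)

    def update_augmentation(self, s0=None, logf0=None, logt1=None, logpsi1=None,
                            logpsi0=None):
        """Partially collapsed sweep for pseudo-species: a -> z -> w -> Omega.

        a_k is drawn from its marginal conditional (z, w summed out as in the
        all-zero unit likelihood), then z and w are drawn compatibly.
        Observed species keep a_k = 1.
        """
        if not self.M:
            raise DataValidationError("update_augmentation requires an augmented spec")
        rng = self.rng
        if s0 is None:
            eta_t = self._eta_theta()
            eta_z = self._eta_psi()
            logt1, logt0 = log_expit(eta_t), log_expit(-eta_t)
            logpsi1, logpsi0 = log_expit(eta_z), log_expit(-eta_z)
            s0 = (log_expit(-self._eta_p()) * self.mask4).sum(axis=2)
            logf0 = np.where(self.has_obs_j, np.logaddexp(logt1 + s0, logt0), 0.0)
        kp = slice(self.K_obs, self.K)
        sumf = logf0[..., kp].sum(axis=1)  # (I, Kp)
        unit0 = np.logaddexp(logpsi1[:, kp] + sumf, logpsi0[:, kp])
        L0 = unit0.sum(axis=0)  # (Kp,)
        om = np.clip(self.omega, 1e-12, 1 - 1e-12)
        log_odds = np.log(om) - np.log1p(-om) + L0
        a_p = rng.random(L0.shape) < 1.0 / (1.0 + np.exp(-log_odds))
        pz0 = np.exp(logpsi1[:, kp] + sumf - unit0)
        z_p = (rng.random(pz0.shape) < pz0) & a_p[None, :]
        pw0 = np.exp(logt1[..., kp] + s0[..., kp] - logf0[..., kp])
        w_p = (rng.random(pw0.shape) < pw0) & z_p[:, None, :]
        self.a[kp] = a_p
        self.z[:, kp] = z_p
        self.w[..., kp] = w_p
        n_in = int(self.a.sum())
        self.omega = rng.beta(1 + n_in, 1 + self.M - n_in)

    # -- species coefficients ----------------------------------------------

    def _block_prior(self, fam, col):
        hcol = 0 if fam == "beta2" else col
        mu = self.mu[fam][self.group_idx, hcol]
        sd = np.maximum(self.sigma[fam][self.group_idx, hcol], _SIGMA_FLOOR)
        return mu, sd

    def _block_ll(self, fam, candidate):
        if fam in ("lpsi", "beta3"):
            return self._ll_psi(**{fam: candidate})
        if fam in ("ltheta", "btheta"):
            return self._ll_theta(**{fam: candidate})
        return self._ll_p(**{fam: candidate})

    def update_species_coefficients(self):
        """One adaptive random-walk Metropolis sweep over every species-level
        coefficient block; pseudo-species with a_k = 0 are refreshed directly
        from the community prior (their likelihood contribution is empty)."""
        rng = self.rng
        active = self.a.astype(bool)
        for fam, col in self.blocks:
            arr = self.coef[fam]
            vec = arr if arr.ndim == 1 else arr[:, col]
            mu, sd = self._block_prior(fam, col)
            noise = rng.standard_normal(self.K)
            prop_vec = vec + self.step[(fam, col)] * noise
            cand = prop_vec if arr.ndim == 1 else _with_col(arr, col, prop_vec)
            with np.errstate(over="ignore", invalid="ignore"):
                ll_cur = self._block_ll(fam, arr)
                ll_prop = self._block_ll(fam, cand)
                delta = (
                    ll_prop - ll_cur
                    - 0.5 * ((prop_vec - mu) / sd) ** 2
                    + 0.5 * ((vec - mu) / sd) ** 2
                )
            delta = np.where(np.isfinite(delta), delta, -np.inf)  # reject bad proposals
            accept = (np.log(rng.random(self.K)) < delta) & active
            vec = np.where(accept, prop_vec, vec)
            # a_k = 0 species: exact Gibbs draw from the hierarchical prior
            if not active.all():
                fresh = rng.normal(mu, sd)
                vec = np.where(active, vec, fresh)
            if arr.ndim == 1:
                self.coef[fam] = vec
            else:
                arr[:, col] = vec
            self.acc[(fam, col)] += accept
        self.att += 1
        if "beta2" in self.coef:
            self._recenter_lp_beta2()

    def _recenter_lp_beta2(self):
        """Exact Gibbs move along the likelihood ridge lp_k + mean(beta2_k).

        Without a corner constraint the detection intercept and the
        categorical level effects are only identified jointly: shifting
        lp_k by d and every beta2_k[l] by -d leaves the likelihood
        unchanged. The full conditional of d comes from the normal priors
        alone and is conjugate; sampling it decorrelates the aliased
        directions that the single-coordinate walks cross slowly.
        """
        lp = self.coef["lp"]
        b2 = self.coef["beta2"]
        L = b2.shape[1]
        mu_lp, sd_lp = self._block_prior("lp", 0)
        mu_b2, sd_b2 = self._block_prior("beta2", 0)
        prec = 1.0 / sd_lp**2 + L / sd_b2**2
        mean = ((mu_lp - lp) / sd_lp**2 + (b2 - mu_b2[:, None]).sum(axis=1) / sd_b2**2) / prec
        delta = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        self.coef["lp"] = lp + delta
        b2 -= delta[:, None]

    # -- hyperparameters ---------------------------------------------------

    def update_hyperparameters(self):
        """Conjugate Gibbs for each community mean; log-scale random walk for
        each community sd with the Uniform(0, upper) prior enforced."""
        rng = self.rng
        m0, v0 = self.prior.mu_mean, self.prior.mu_var
        upper = self.prior.sigma_upper
        for fam, ncols in self.families.items():
            arr = self.coef[fam]
            for g in range(self.n_groups):
                members = self.group_idx == g
                for hcol in range(ncols):
                    if fam == "beta2":
                        vals = arr[members, :].ravel()
                    elif arr.ndim == 1:
                        vals = arr[members]
                    else:
                        vals = arr[members, hcol]
                    n = vals.size
                    sig = max(self.sigma[fam][g, hcol], _SIGMA_FLOOR)
                    post_var = 1.0 / (1.0 / v0 + n / sig**2)
                    post_mean = post_var * (m0 / v0 + vals.sum() / sig**2)
                    mu_new = rng.normal(post_mean, np.sqrt(post_var))
                    self.mu[fam][g, hcol] = mu_new

                    cur = self.sigma[fam][g, hcol]
                    prop = cur * np.exp(self.hyper_step[fam][g, hcol] * rng.standard_normal())
                    if _SIGMA_FLOOR < prop < upper:
                        sq = ((vals - mu_new) ** 2).sum()
                        ll_cur = -n * np.log(max(cur, _SIGMA_FLOOR)) - 0.5 * sq / max(cur, _SIGMA_FLOOR) ** 2
                        ll_prop = -n * np.log(prop) - 0.5 * sq / prop**2
                        # Jacobian of the log-scale walk: + log(prop/cur)
                        if np.log(rng.random()) < ll_prop - ll_cur + np.log(prop / cur):
                            self.sigma[fam][g, hcol] = prop
                            self.hyper_acc[fam][g, hcol] += 1
        self._interweave_sigma()
        if "beta2" in self.coef:
            self._recenter_mu_lp_beta2()
        self.hyper_att += 1

    def _recenter_mu_lp_beta2(self):
        """Community-level companion of the lp/beta2 recentring: shift
        (mu_lp, every lp_k) by e and (mu_beta2, every beta2_k[l]) by -e.
        Likelihood and species-level prior deviations are invariant, so the
        exact conditional of e comes from the two mu hyperpriors alone."""
        m0, v0 = self.prior.mu_mean, self.prior.mu_var
        for g in range(self.n_groups):
            members = self.group_idx == g
            mu_lp = self.mu["lp"][g, 0]
            mu_b2 = self.mu["beta2"][g, 0]
            mean = ((m0 - mu_lp) + (mu_b2 - m0)) / 2.0
            eps = self.rng.normal(mean, np.sqrt(v0 / 2.0))
            self.mu["lp"][g, 0] += eps
            self.mu["beta2"][g, 0] -= eps
            self.coef["lp"][members] += eps
            self.coef["beta2"][members, :] -= eps

    def _interweave_sigma(self):
        """Non-centered (ancillarity-sufficiency interweaving) rescaling move.

        In the non-centered parameterization c_k = mu + sigma * u_k with
        u_k ~ N(0, 1) fixed, a log-scale random walk on sigma rescales every
        species coefficient of the family jointly and is accepted against the
        complete-data likelihood.  This traverses the funnel that the
        centered updates cross only slowly when sigma is near zero.
        """
        rng = self.rng
        upper = self.prior.sigma_upper
        for fam, ncols in self.families.items():
            arr = self.coef[fam]
            for g in range(self.n_groups):
                members = self.group_idx == g
                for hcol in range(ncols):
                    mu = self.mu[fam][g, hcol]
                    cur = self.sigma[fam][g, hcol]
                    prop = cur * np.exp(self.nc_step[fam][g, hcol] * rng.standard_normal())
                    if not _SIGMA_FLOOR < prop < upper:
                        continue
                    scale = prop / cur
                    cand = arr.copy()
                    if fam == "beta2":
                        cand[members, :] = mu + scale * (arr[members, :] - mu)
                    elif arr.ndim == 1:
                        cand[members] = mu + scale * (arr[members] - mu)
                    else:
                        cand[members, hcol] = mu + scale * (arr[members, hcol] - mu)
                    with np.errstate(over="ignore", invalid="ignore"):
                        delta = self._block_ll(fam, cand) - self._block_ll(fam, arr)
                    delta = np.where(np.isfinite(delta), delta, -np.inf)
                    dsum = float(delta[members].sum())
                    # u's N(0,1) density is unchanged; Jacobian of the
                    # log-scale walk contributes log(prop/cur)
                    if np.log(rng.random()) < dsum + np.log(scale):
                        self.coef[fam] = cand
                        self.sigma[fam][g, hcol] = prop
                        self.nc_acc[fam][g, hcol] += 1

    # -- adaptation --------------------------------------------------------

    def adapt(self, batch_number):
        gain = min(0.5, 2.0 * batch_number**-0.5)
        target = 0.44
        for b in self.blocks:
            rate = self.acc[b] / max(self.att, 1)
            self.step[b] *= np.exp(gain * (rate - target))
            self.acc[b][:] = 0.0
        for fam in self.families:
            rate = self.hyper_acc[fam] / max(self.hyper_att, 1)
            self.hyper_step[fam] *= np.exp(gain * (rate - target))
            self.hyper_acc[fam][:] = 0.0
            nc_rate = self.nc_acc[fam] / max(self.hyper_att, 1)
            self.nc_step[fam] *= np.exp(gain * (nc_rate - target))
            self.nc_acc[fam][:] = 0.0
        self.att = 0
        self.hyper_att = 0

    def sweep(self):
        self.update_latent_states()
        self.update_species_coefficients()
        self.update_hyperparameters()


def _with_col(arr, col, vec):
    out = arr.copy()
    out[:, col] = vec
    return out


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------


def _build_group_index(data: DetectionArray, spec: ModelSpec):
    if spec.group_map is None:
        return np.zeros(data.n_species, dtype=np.intp), 1, None
    labels = sorted({spec.group_map[s] for s in data.species_labels[: data.n_observed_species]})
    lut = {g: i for i, g in enumerate(labels)}
    idx = np.array([lut[spec.group_map[s]] for s in data.species_labels], dtype=np.intp)
    return idx, len(labels), labels


def run_mcmc(data: DetectionArray, cov: CovariateSet, spec: ModelSpec,
             config: McmcConfig | None = None) -> PosteriorSamples:
    """Fit the model by MCMC; returns thinned post-burn-in draws.

    Expects continuous covariates to be standardized already (the estimator
    facade does this).  Identical (data, covariates, spec, config) including
    the seed reproduce bit-identical draws.
    """
    config = config or McmcConfig()
    spec.validate(data, cov)
    fingerprint = data.fingerprint()
    if spec.augmentation_M:
        data = data.augment(spec.augmentation_M)
    design = build_design(data.shape, cov, spec)
    group_idx, n_groups, group_labels = _build_group_index(data, spec)

    S = config.n_saved
    if S < 1:
        raise DataValidationError("config yields zero saved draws; lengthen the run")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    draws = None
    acc_totals = {}
    for c, seed_c in enumerate(seeds):
        state = ChainState(data, design, spec, group_idx, n_groups,
                           np.random.default_rng(seed_c))
        if draws is None:
            draws = _allocate(config.n_chains, S, state)
        saved = 0
        post_acc = {b: np.zeros(state.K) for b in state.blocks}
        post_att = 0
        for it in range(config.n_iterations):
            state.sweep()
            if it < config.burn_in:
                if (it + 1) % config.adapt_interval == 0:
                    state.adapt((it + 1) // config.adapt_interval)
                if it == config.burn_in - 1:
                    for b in state.blocks:
                        state.acc[b][:] = 0.0
                    state.att = 0
            else:
                if saved < S and (it - config.burn_in) % config.thin == config.thin - 1:
                    _record(draws, c, saved, state)
                    saved += 1
        for b in state.blocks:
            key = f"{b[0]}[{b[1]}]" if b[0] not in ("lpsi", "ltheta", "lp") else b[0]
            acc_totals.setdefault(key, []).append(state.acc[b].mean() / max(state.att, 1))

    acceptance = {k: float(np.mean(v)) for k, v in acc_totals.items()}
    return PosteriorSamples(
        draws=draws,
        species_labels=list(data.species_labels),
        n_observed_species=data.n_observed_species,
        spec=spec,
        config=config,
        group_labels=group_labels,
        acceptance=acceptance,
        data_fingerprint=fingerprint,
    )


def _allocate(C, S, state: ChainState):
    draws = {}
    for fam, arr in state.coef.items():
        draws[fam] = np.empty((C, S) + arr.shape)
    for fam in state.families:
        nc = state.mu[fam].shape
        draws[f"mu_{fam}"] = np.empty((C, S) + nc)
        draws[f"sigma_{fam}"] = np.empty((C, S) + nc)
    draws["z"] = np.empty((C, S, state.I, state.K), dtype=np.int8)
    draws["w"] = np.empty((C, S, state.I, state.J, state.K), dtype=np.int8)
    if state.M:
        draws["a"] = np.empty((C, S, state.K), dtype=np.int8)
        draws["N"] = np.empty((C, S))
        draws["omega"] = np.empty((C, S))
    return draws


def _record(draws, c, s, state: ChainState):
    for fam, arr in state.coef.items():
        draws[fam][c, s] = arr
    for fam in state.families:
        draws[f"mu_{fam}"][c, s] = state.mu[fam]
        draws[f"sigma_{fam}"][c, s] = state.sigma[fam]
    draws["z"][c, s] = state.z
    draws["w"][c, s] = state.w
    if state.M:
        draws["a"][c, s] = state.a
        draws["N"][c, s] = state.a.sum()
        draws["omega"][c, s] = state.omega


# --------------------------------------------------------------------------
# richness summaries
# --------------------------------------------------------------------------


def posterior_richness(samples: PosteriorSamples, mass: float = 0.95):
    """Summarize posterior species richness N = sum(a_k) from an augmented fit.

    Returns a dict with the posterior mean, HDI, P(N = m) for m = 0..M, and
    the posterior for the number of species missed by the survey
    (N - K_observed).
    """
    if "N" not in samples.draws:
        raise DataValidationError("richness summary requires an augmented fit (M > 0)")
    N = samples.stacked("N").astype(int)
    M = samples.spec.augmentation_M
    from .assessment import hdi

    lo, hi = hdi(N, mass=mass)
    pmf = np.bincount(N, minlength=M + 1) / N.size
    miss = N - samples.n_observed_species
    mlo, mhi = hdi(miss, mass=mass)
    return {
        "mean": float(N.mean()),
        "hdi": (float(lo), float(hi)),
        "pmf": pmf,
        "M": M,
        "n_observed": samples.n_observed_species,
        "undetected_mean": float(miss.mean()),
        "undetected_hdi": (float(mlo), float(mhi)),
    }


def check_augmentation_sufficiency(samples: PosteriorSamples, tail_prob: float = 0.01):
    """Is the augmentation bound M comfortably above the richness posterior?

    Sufficient when P(N >= M - 1) < tail_prob, i.e. M sits in the far right
    tail of the posterior of N.  Returns (sufficient, report).
    """
    if "N" not in samples.draws:
        raise DataValidationError("augmentation check requires an augmented fit (M > 0)")
    N = samples.stacked("N")
    M = samples.spec.augmentation_M
    p_tail = float(np.mean(N >= M - 1))
    report = {
        "M": M,
        "tail_prob": p_tail,
        "tail_mass_at_M": float(np.mean(N == M)),
        "threshold": tail_prob,
        "posterior_mean": float(N.mean()),
    }
    return p_tail < tail_prob, report


__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "ChainState",
    "z_full_conditional_prob",
    "w_full_conditional_prob",
    "a_full_conditional_prob",
    "run_mcmc",
    "posterior_richness",
    "check_augmentation_sufficiency",
]
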