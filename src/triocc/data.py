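"""Core domain containers for multi-scale occupancy data.

The observational unit is a binary detection ``y[i, j, r, k]``: species ``k``
detected (1) or not (0) in technical replicate ``r`` of biological sample
``j`` collected at site ``i``.  Three container types travel together through
the package:

``DetectionArray``
    the 4-D detection/non-detection array plus an observed-cell mask that
    supports ragged designs (failed replicates, unequal sampling effort);
``CovariateSet``
    site-, sample- and replicate-level covariates with the z-scoring metadata
    needed to back-transform effect estimates;
``ModelSpec``
    which covariates act at which level, the data-augmentation size, optional
    species grouping, and prior settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np


class DataValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


# --------------------------------------------------------------------------
# detection data
# --------------------------------------------------------------------------


@dataclass
class DetectionArray:
    """Binary detections over (site, sample, replicate, species).

    Parameters
    ----------
    y : ndarray of shape (I, J, R, K)
        Detection (1) / non-detection (0) indicators.
    observed_mask : ndarray of bool, same shape, optional
        True for cells that were actually observed.  Masked-out cells are
        ignored by every likelihood computation.  Defaults to all observed.
    """

    y: np.ndarray
    observed_mask: np.ndarray | None = None
    site_labels: list[str] | None = None
    sample_labels: list[str] | None = None
    replicate_labels: list[str] | None = None
    species_labels: list[str] | None = None
    n_pseudo: int = 0  # trailing all-zero species appended by augmentation
    # internal subsets (CV folds, held-out sites) may carry all-zero species
    require_detected: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 4:
            raise DataValidationError(
                f"y must be 4-D (site, sample, replicate, species); got ndim={self.y.ndim}"
            )
        I, J, R, K = self.y.shape
        if min(I, J, R, K) < 1:
            raise DataValidationError(f"all dimensions must be >= 1; got shape {self.y.shape}")
        if self.observed_mask is None:
            self.observed_mask = np.ones(self.y.shape, dtype=bool)
        else:
            self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
            if self.observed_mask.shape != self.y.shape:
                raise DataValidationError("observed_mask shape must match y")
        obs = self.y[self.observed_mask]
        if obs.size and not np.isin(obs, (0, 1)).all():
            raise DataValidationError("observed y entries must be 0 or 1")
        if (self.y[~self.observed_mask] != 0).any():
            raise DataValidationError("masked-out cells must carry y = 0")
        defaults = {
            "site_labels": [f"site_{i + 1}" for i in range(I)],
            "sample_labels": [f"sample_{j + 1}" for j in range(J)],
            "replicate_labels": [f"rep_{r + 1}" for r in range(R)],
            "species_labels": [f"sp_{k + 1}" for k in range(K)],
        }
        for name, default in defaults.items():
            val = getattr(self, name)
            if val is None:
                setattr(self, name, default)
            elif len(val) != len(default):
                raise DataValidationError(f"{name} length must match array dimension")
        # every *observed* (non-pseudo) species must have >= 1 detection
        K_obs = K - self.n_pseudo
        detected = self.y[..., :K_obs].reshape(-1, K_obs).any(axis=0)
        if self.require_detected and K_obs and not detected.all():
            missing = [self.species_labels[k] for k in np.flatnonzero(~detected)]
            raise DataValidationError(
                "species with zero detections are not observable units "
                f"(augment explicitly instead): {missing}"
            )

    @property
    def shape(self):
        return self.y.shape

    @property
    def n_sites(self):
        return self.y.shape[0]

    @property
    def n_samples(self):
        return self.y.shape[1]

    @property
    def n_replicates(self):
        return self.y.shape[2]

    @property
    def n_species(self):
        return self.y.shape[3]

    @property
    def n_observed_species(self):
        return self.y.shape[3] - self.n_pseudo

    def augment(self, M: int) -> "DetectionArray":
        """Append all-zero pseudo-species up to a total of M species rows.

        Data augmentation for unknown richness: M - K pseudo-species with
        inclusion indicators estimated by the sampler.
        """
        K_obs = self.n_observed_species
        if self.n_pseudo:
            raise DataValidationError("detection array is already augmented")
        if M <= K_obs:
            raise DataValidationError(
                f"augmentation size M={M} must exceed the {K_obs} observed species"
            )
        I, J, R, _ = self.y.shape
        extra = M - K_obs
        y = np.concatenate([self.y, np.zeros((I, J, R, extra), dtype=np.int8)], axis=3)
        # pseudo-species inherit the replicate-level observation pattern
        cell_mask = self.observed_mask.any(axis=3, keepdims=True)
        mask = np.concatenate(
            [self.observed_mask, np.broadcast_to(cell_mask, (I, J, R, extra))], axis=3
        )
        labels = list(self.species_labels) + [f"aug_{m + 1}" for m in range(extra)]
        return DetectionArray(
            y=y,
            observed_mask=mask,
            site_labels=self.site_labels,
            sample_labels=self.sample_labels,
            replicate_labels=self.replicate_labels,
            species_labels=labels,
            n_pseudo=extra,
        )

    def subset_sites(self, site_idx) -> "DetectionArray":
        site_idx = np.asarray(site_idx)
        return DetectionArray(
            y=self.y[site_idx],
            observed_mask=self.observed_mask[site_idx],
            site_labels=[self.site_labels[i] for i in site_idx],
            sample_labels=self.sample_labels,
            replicate_labels=self.replicate_labels,
            species_labels=self.species_labels,
            n_pseudo=self.n_pseudo,
            require_detected=False,
        )

    def drop_species(self, drop_idx) -> "DetectionArray":
        keep = [k for k in range(self.n_species) if k not in set(np.atleast_1d(drop_idx))]
        if not keep:
            raise DataValidationError("cannot drop every species")
        return DetectionArray(
            y=self.y[..., keep],
            observed_mask=self.observed_mask[..., keep],
            site_labels=self.site_labels,
            sample_labels=self.sample_labels,
            replicate_labels=self.replicate_labels,
            species_labels=[self.species_labels[k] for k in keep],
            n_pseudo=sum(k >= self.n_observed_species for k in keep),
        )

    def fingerprint(self) -> str:
        """Stable hash of the observed data, used to guard model comparisons."""
        h = hashlib.sha256()
        h.update(self.y.tobytes())
        h.update(self.observed_mask.tobytes())
        h.update(json.dumps(self.species_labels[: self.n_observed_species]).encode())
        return h.hexdigest()[:16]


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------


@dataclass
class CategoricalCovariate:
    """Integer level codes with their labels (codes in [0, L-1])."""

    codes: np.ndarray
    levels: list[str]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.intp)
        L = len(self.levels)
        if L < 1:
            raise DataValidationError("categorical covariate needs >= 1 level")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= L):
            raise DataValidationError(
                f"level codes must lie in [0, {L - 1}] for {L} declared levels"
            )

    @property
    def n_levels(self):
        return len(self.levels)


@dataclass
class CovariateSet:
    """Covariates at the three levels of the design.

    site_continuous      : name -> (I,) values (e.g. water depth in m)
    sample_continuous    : name -> (I, J) values
    replicate_continuous : name -> (I, J, R) values (e.g. sequencing depth)
    replicate_categorical: name -> CategoricalCovariate over (I, J, R)
                           (e.g. amplicon identity)
    standardization      : name -> (mean, sd) recorded at z-scoring time
    """

    site_continuous: dict = field(default_factory=dict)
    sample_continuous: dict = field(default_factory=dict)
    replicate_continuous: dict = field(default_factory=dict)
    replicate_categorical: dict = field(default_factory=dict)
    standardization: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.site_continuous, self.sample_continuous, self.replicate_continuous):
            for name, v in d.items():
                d[name] = np.asarray(v, dtype=float)

    def level_of(self, name: str) -> str:
        for level, d in (
            ("site", self.site_continuous),
            ("sample", self.sample_continuous),
            ("replicate", self.replicate_continuous),
            ("replicate_categorical", self.replicate_categorical),
        ):
            if name in d:
                return level
        raise KeyError(f"unknown covariate: {name!r}")

    def names(self):
        return (
            list(self.site_continuous)
            + list(self.sample_continuous)
            + list(self.replicate_continuous)
            + list(self.replicate_categorical)
        )

    def subset_sites(self, site_idx) -> "CovariateSet":
        site_idx = np.asarray(site_idx)
        return CovariateSet(
            site_continuous={k: v[site_idx] for k, v in self.site_continuous.items()},
            sample_continuous={k: v[site_idx] for k, v in self.sample_continuous.items()},
            replicate_continuous={k: v[site_idx] for k, v in self.replicate_continuous.items()},
            replicate_categorical={
                k: CategoricalCovariate(v.codes[site_idx], v.levels)
                for k, v in self.replicate_categorical.items()
            },
            standardization=dict(self.standardization),
        )


def standardize_covariates(cov: CovariateSet, mask: np.ndarray | None = None) -> CovariateSet:
    """z-score every continuous covariate to mean 0, sd 1 (sample sd, n-1).

    ``mask`` (optional) marks observed replicate cells with shape (I, J, R);
    replicate- and sample-level statistics are then computed over observed
    cells only.  Stored (mean, sd) pairs allow back-transformation.
    Categorical covariates pass through unchanged.  Raises on a constant
    covariate (sd = 0).
    """

    def _std(name, values, obs):
        vals = values[obs] if obs is not None else values.ravel()
        if np.unique(vals).size < 2:
            raise DataValidationError(f"constant covariate {name!r}: cannot z-score (sd = 0)")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        return (values - mean) / sd, (mean, sd)

    std = {}
    site = {}
    for name, v in cov.site_continuous.items():
        site[name], std[name] = _std(name, v, None)
    sample = {}
    smask = mask.any(axis=2) if mask is not None else None
    for name, v in cov.sample_continuous.items():
        sample[name], std[name] = _std(name, v, smask)
    repl = {}
    for name, v in cov.replicate_continuous.items():
        repl[name], std[name] = _std(name, v, mask)
    return CovariateSet(
        site_continuous=site,
        sample_continuous=sample,
        replicate_continuous=repl,
        replicate_categorical=dict(cov.replicate_categorical),
        standardization=std,
    )


def destandardize(cov: CovariateSet, name: str, values):
    """Map standardized values back to the original covariate scale."""
    mean, sd = cov.standardization[name]
    return np.asarray(values) * sd + mean


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorConfig:
    """Community-level hyperpriors.

    Every community mean gets mu ~ Normal(mu_mean, mu_var) (second argument a
    variance) and every community sd gets sigma ~ Uniform(0, sigma_upper).
    """

    mu_mean: float = 0.0
    mu_var: float = 10.0
    sigma_upper: float = 5.0


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates act at which level, plus augmentation and grouping.

    psi_covariates   : site-level continuous covariates on occupancy
    theta_covariates : sample-level continuous covariates on capture
    p_covariates     : replicate-level covariates (continuous and/or one
                       categorical) on detection
    augmentation_M   : 0 for known richness, else total species rows >= K
    group_map        : optional species label -> group label (e.g. phylum);
                       switches community hyperparameters to group-indexed
    """

    psi_covariates: tuple = ()
    theta_covariates: tuple = ()
    p_covariates: tuple = ()
    augmentation_M: int = 0
    group_map: dict | None = None
    priors: PriorConfig = PriorConfig()
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "psi_covariates", tuple(self.psi_covariates))
        object.__setattr__(self, "theta_covariates", tuple(self.theta_covariates))
        object.__setattr__(self, "p_covariates", tuple(self.p_covariates))

    def validate(self, data: DetectionArray, cov: CovariateSet) -> None:
        for name in self.psi_covariates:
            if cov.level_of(name) != "site":
                raise DataValidationError(f"occupancy covariate {name!r} must be site-level")
        for name in self.theta_covariates:
            if cov.level_of(name) != "sample":
                raise DataValidationError(f"capture covariate {name!r} must be sample-level")
        n_cat = 0
        for name in self.p_covariates:
            lvl = cov.level_of(name)
            if lvl == "replicate_categorical":
                n_cat += 1
            elif lvl != "replicate":
                raise DataValidationError(f"detection covariate {name!r} must be replicate-level")
        if n_cat > 1:
            raise DataValidationError("at most one categorical detection covariate is supported")
        if self.augmentation_M:
            if self.augmentation_M <= data.n_observed_species:
                raise DataValidationError(
                    f"augmentation_M={self.augmentation_M} must exceed the "
                    f"{data.n_observed_species} observed species"
                )
            if self.group_map is not None:
                raise DataValidationError(
                    "group-level hyperparameters and richness augmentation cannot be combined"
                )
        if self.group_map is not None:
            counts = {}
            for k in range(data.n_observed_species):
                sp = data.species_labels[k]
                if sp not in self.group_map:
                    raise DataValidationError(f"species {sp!r} missing from group_map")
                counts[self.group_map[sp]] = counts.get(self.group_map[sp], 0) + 1
            bad = [g for g, c in counts.items() if c < 2]
            if bad:
                raise DataValidationError(
                    f"every group needs >= 2 modelled species; offending groups: {bad}"
                )

    def label_or_formula(self) -> str:
        if self.label:
            return self.label
        f = lambda xs: ", ".join(xs) if xs else "."  # noqa: E731
        return (
            f"psi({f(self.psi_covariates)}) theta({f(self.theta_covariates)}) "
            f"p({f(self.p_covariates)})"
        )


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

COEF_FAMILIES = ("lpsi", "ltheta", "lp", "beta1", "beta2", "beta3", "btheta")


@dataclass
class SpeciesParams:
    """Species-level logit-scale parameters (arrays over K species).

    lpsi, ltheta, lp : intercepts for occupancy, capture, detection
    beta1 : (K, n_cont_p) detection slopes on continuous replicate covariates
    beta2 : (K, L) detection effects per categorical level
    beta3 : (K, n_cont_psi) occupancy slopes on site covariates
    btheta: (K, n_cont_theta) capture slopes on sample covariates
    a     : inclusion indicators (always 1 for observed species)
    """

    lpsi: np.ndarray
    ltheta: np.ndarray
    lp: np.ndarray
    beta1: np.ndarray | None = None
    beta2: np.ndarray | None = None
    beta3: np.ndarray | None = None
    btheta: np.ndarray | None = None
    a: np.ndarray | None = None

    def __post_init__(self):
        K = len(np.atleast_1d(self.lpsi))
        self.lpsi = np.asarray(self.lpsi, dtype=float).reshape(K)
        self.ltheta = np.asarray(self.ltheta, dtype=float).reshape(K)
        self.lp = np.asarray(self.lp, dtype=float).reshape(K)
        for name in ("beta1", "beta2", "beta3", "btheta"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.ndim == 1:
                    v = v[:, None]
                setattr(self, name, v)
        if self.a is None:
            self.a = np.ones(K, dtype=np.int8)
        else:
            self.a = np.asarray(self.a, dtype=np.int8).reshape(K)
        for arr in (self.lpsi, self.ltheta, self.lp, self.beta1, self.beta2, self.beta3, self.btheta):
            if arr is not None and not np.isfinite(arr).all():
                raise DataValidationError("species parameters must be finite")

    @property
    def n_species(self):
        return self.lpsi.shape[0]


@dataclass
class CommunityParams:
    """Community-level means/sds per coefficient family, optionally grouped.

    mu[name] and sigma[name] are arrays over groups (length 1 when no
    grouping).  omega is the augmented-model inclusion probability.
    """

    mu: dict
    sigma: dict
    omega: float | None = None

    def __post_init__(self):
        self.mu = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.mu.items()}
        self.sigma = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.sigma.items()}
        for name, s in self.sigma.items():
            if (s < 0).any():
                raise DataValidationError(f"sigma[{name}] must be >= 0")
        if self.omega is not None and not 0.0 <= self.omega <= 1.0:
            raise DataValidationError("omega must lie in [0, 1]")


@dataclass
class LatentStates:
    """Binary latent occupancy z (I, K) and capture w (I, J, K) states."""

    z: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.w = np.asarray(self.w, dtype=np.int8)
        if self.w.shape[0] != self.z.shape[0] or self.w.shape[2] != self.z.shape[1]:
            raise DataValidationError("w must have shape (I, J, K) matching z (I, K)")
        if (self.w > self.z[:, None, :]).any():
            raise DataValidationError("capture without occupancy: w > z")

    def check_against(self, data: DetectionArray) -> None:
        y_any = (data.y * data.observed_mask).any(axis=2)
        if (y_any > self.w).any():
            raise DataValidationError("detection without capture: y > w")


__all__ = [
    "DetectionArray",
    "CategoricalCovariate",
    "CovariateSet",
    "standardize_covariates",
    "destandardize",
    "PriorConfig",
    "ModelSpec",
    "SpeciesParams",
    "CommunityParams",
    "LatentStates",
    "DataValidationError",
    "COEF_FAMILIES",
]
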