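"""Readers and writers for the long-format table dialect.

Detection tables are tidy CSV/TSV with columns
``site, sample, replicate, species, detected`` (one row per cell);
covariates travel in a site table (``site, name, value``) and a replicate
table (``site, sample, replicate, name, value``).  Categorical covariate
values are non-numeric strings.  Everything the package writes it can read
back identically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import (
    CategoricalCovariate,
    CovariateSet,
    DataValidationError,
    DetectionArray,
)

log = logging.getLogger("triocc")

DETECTION_COLUMNS = ["site", "sample", "replicate", "species", "detected"]


def _read_table(path):
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def _first_appearance(values):
    return list(dict.fromkeys(values))


def read_detection_table(path, absent_rows: str = "zero") -> DetectionArray:
    """Read a long-format detection table into a dense DetectionArray.

    Labels keep first-appearance order.  Cells without a row become y = 0
    under ``absent_rows="zero"`` or masked-out (unobserved) under
    ``absent_rows="missing"``.  Duplicate (site, sample, replicate, species)
    rows and non-binary ``detected`` values raise.
    """
    if absent_rows not in ("zero", "missing"):
        raise DataValidationError("absent_rows must be 'zero' or 'missing'")
    df = _read_table(path)
    missing_cols = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"detection table missing column(s): {missing_cols}")
    if not df["detected"].isin(["0", "1"]).all():
        bad = df.loc[~df["detected"].isin(["0", "1"]), "detected"].unique()[:5]
        raise DataValidationError(f"non-binary detected values: {list(bad)}")
    keys = df[["site", "sample", "replicate", "species"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise DataValidationError(f"duplicate detection row for cell {dup}")

    sites = _first_appearance(df["site"])
    samples = _first_appearance(df["sample"])
    reps = _first_appearance(df["replicate"])
    species = _first_appearance(df["species"])
    shape = (len(sites), len(samples), len(reps), len(species))
    y = np.zeros(shape, dtype=np.int8)
    mask = np.zeros(shape, dtype=bool) if absent_rows == "missing" else np.ones(shape, dtype=bool)
    idx = {
        "site": {s: i for i, s in enumerate(sites)},
        "sample": {s: i for i, s in enumerate(samples)},
        "replicate": {s: i for i, s in enumerate(reps)},
        "species": {s: i for i, s in enumerate(species)},
    }
    ii = df["site"].map(idx["site"]).to_numpy()
    jj = df["sample"].map(idx["sample"]).to_numpy()
    rr = df["replicate"].map(idx["replicate"]).to_numpy()
    kk = df["species"].map(idx["species"]).to_numpy()
    y[ii, jj, rr, kk] = df["detected"].astype(np.int8).to_numpy()
    if absent_rows == "missing":
        mask[ii, jj, rr, kk] = True
    return DetectionArray(
        y=y, observed_mask=mask, site_labels=sites, sample_labels=samples,
        replicate_labels=reps, species_labels=species,
    )


def write_detection_table(data: DetectionArray, path, include_masked: bool = False):
    """Write the long-format dialect read_detection_table consumes.

    Masked-out cells are omitted (so a round-trip with
    ``absent_rows="missing"`` restores the mask)."""
    I, J, R, K = data.shape
    ii, jj, rr, kk = np.where(data.observed_mask | include_masked)
    df = pd.DataFrame(
        {
            "site": np.asarray(data.site_labels)[ii],
            "sample": np.asarray(data.sample_labels)[jj],
            "replicate": np.asarray(data.replicate_labels)[rr],
            "species": np.asarray(data.species_labels)[kk],
            "detected": data.y[ii, jj, rr, kk],
        }
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, index=False, sep=sep)
    return df


def read_covariates(site_path=None, replicate_path=None, data: DetectionArray | None = None,
                    sample_level: tuple = ()) -> CovariateSet:
    """Assemble a CovariateSet from site and replicate covariate tables.

    The site table has columns (site, name, value); the replicate table
    (site, sample, replicate, name, value).  Values parseable as floats
    become continuous covariates; anything else becomes a categorical
    covariate with labelled levels.  Names listed in ``sample_level`` are
    averaged over replicates into sample-level (I, J) covariates.
    ``data`` supplies the label ordering.
    """
    if data is None:
        raise DataValidationError("read_covariates needs the DetectionArray for label order")
    cov = CovariateSet()
    if site_path is not None:
        df = _read_table(site_path)
        for c in ("site", "name", "value"):
            if c not in df.columns:
                raise DataValidationError(f"site covariate table missing column {c!r}")
        site_idx = {s: i for i, s in enumerate(data.site_labels)}
        for name, sub in df.groupby("name", sort=False):
            vec = np.full(data.n_sites, np.nan)
            for _, row in sub.iterrows():
                if row["site"] not in site_idx:
                    raise DataValidationError(f"unknown site {row['site']!r} in covariates")
                vec[site_idx[row["site"]]] = float(row["value"])
            if np.isnan(vec).any():
                raise DataValidationError(f"site covariate {name!r} missing some sites")
            cov.site_continuous[name] = vec
    if replicate_path is not None:
        df = _read_table(replicate_path)
        for c in ("site", "sample", "replicate", "name", "value"):
            if c not in df.columns:
                raise DataValidationError(f"replicate covariate table missing column {c!r}")
        sidx = {s: i for i, s in enumerate(data.site_labels)}
        jidx = {s: i for i, s in enumerate(data.sample_labels)}
        ridx = {s: i for i, s in enumerate(data.replicate_labels)}
        shape = data.shape[:3]
        for name, sub in df.groupby("name", sort=False):
            numeric = pd.to_numeric(sub["value"], errors="coerce")
            ii = sub["site"].map(sidx).to_numpy()
            jj = sub["sample"].map(jidx).to_numpy()
            rr = sub["replicate"].map(ridx).to_numpy()
            if numeric.notna().all():
                arr = np.full(shape, np.nan)
                arr[ii, jj, rr] = numeric.to_numpy()
                if np.isnan(arr).all(axis=None):
                    raise DataValidationError(f"covariate {name!r} is empty")
                # unobserved cells may stay NaN only if masked out everywhere
                if np.isnan(arr).any():
                    obs = data.observed_mask.any(axis=3)
                    if np.isnan(arr[obs]).any():
                        raise DataValidationError(
                            f"replicate covariate {name!r} missing for observed cells"
                        )
                    arr = np.nan_to_num(arr, nan=np.nanmean(arr))
                if name in sample_level:
                    cov.sample_continuous[name] = arr.mean(axis=2)
                else:
                    cov.replicate_continuous[name] = arr
            else:
                levels = _first_appearance(sub["value"])
                lut = {v: i for i, v in enumerate(levels)}
                codes = np.zeros(shape, dtype=np.intp)
                codes[ii, jj, rr] = sub["value"].map(lut).to_numpy()
                cov.replicate_categorical[name] = CategoricalCovariate(codes, levels)
    return cov


def write_covariates(cov: CovariateSet, data: DetectionArray, site_path=None,
                     replicate_path=None):
    """Inverse of read_covariates for the same label ordering."""
    if site_path is not None:
        rows = [
            {"site": s, "name": name, "value": vec[i]}
            for name, vec in cov.site_continuous.items()
            for i, s in enumerate(data.site_labels)
        ]
        pd.DataFrame(rows).to_csv(site_path, index=False)
    if replicate_path is not None:
        rows = []
        for name, arr in cov.replicate_continuous.items():
            for i, s in enumerate(data.site_labels):
                for j, b in enumerate(data.sample_labels):
                    for r, rep in enumerate(data.replicate_labels):
                        rows.append({"site": s, "sample": b, "replicate": rep,
                                     "name": name, "value": arr[i, j, r]})
        for name, cc in cov.replicate_categorical.items():
            for i, s in enumerate(data.site_labels):
                for j, b in enumerate(data.sample_labels):
                    for r, rep in enumerate(data.replicate_labels):
                        rows.append({"site": s, "sample": b, "replicate": rep,
                                     "name": name, "value": cc.levels[cc.codes[i, j, r]]})
        pd.DataFrame(rows).to_csv(replicate_path, index=False)


def read_group_table(path) -> dict:
    """Species -> group mapping from a two-column (species, group) table."""
    df = _read_table(path)
    for c in ("species", "group"):
        if c not in df.columns:
            raise DataValidationError(f"group table missing column {c!r}")
    return dict(zip(df["species"], df["group"]))


def filter_groups_min_species(data: DetectionArray, group_map: dict, min_k: int = 2,
                              unmapped: str = "error"):
    """Drop species whose group has fewer than ``min_k`` detected species.

    Implements the inclusion rule for group-level (phylum) models: only
    groups in which at least ``min_k`` species were detected are retained.
    Unmapped species either raise (default) or are dropped
    (``unmapped="drop"``).  Returns (filtered DetectionArray, filtered
    group_map) and logs what was removed.
    """
    if unmapped not in ("error", "drop"):
        raise DataValidationError("unmapped must be 'error' or 'drop'")
    labels = data.species_labels[: data.n_observed_species]
    drop = []
    for k, sp in enumerate(labels):
        if sp not in group_map:
            if unmapped == "error":
                raise DataValidationError(f"species {sp!r} missing from group mapping")
            drop.append(k)
    counts = {}
    for k, sp in enumerate(labels):
        if k in drop:
            continue
        counts[group_map[sp]] = counts.get(group_map[sp], 0) + 1
    small = {g for g, c in counts.items() if c < min_k}
    for k, sp in enumerate(labels):
        if k not in drop and group_map[sp] in small:
            drop.append(k)
    if len(drop) == len(labels):
        raise DataValidationError("group filter would remove every species")
    if drop:
        removed = [labels[k] for k in sorted(drop)]
        log.info("group filter removed %d species: %s", len(removed), removed)
        data = data.drop_species(sorted(drop))
    fmap = {sp: group_map[sp] for sp in data.species_labels[: data.n_observed_species]}
    return data, fmap


def write_posterior_summary(samples, path=None) -> pd.DataFrame:
    """Species-level posterior summary table (CSV with fixed column order).

    Per species: posterior mean and 95% HDI of occupancy, capture and
    detection probability at mean covariate values (standardized 0;
    categorical effects averaged over levels), followed by community-mean
    rows (inverse-logit of the mu draws).
    """
    from ._util import inv_logit
    from .assessment import hdi

    rows = []
    K = samples.n_observed_species
    lpsi = samples.stacked("lpsi")[:, :K]
    ltheta = samples.stacked("ltheta")[:, :K]
    lp = samples.stacked("lp")[:, :K]
    if "beta2" in samples.draws:  # categorical detection effects: level-average
        lp = lp + samples.stacked("beta2")[:, :K, :].mean(axis=2)

    def summarize(label, kind, draws):
        lo, hi = hdi(draws)
        return {"label": label, "kind": kind, "mean": float(draws.mean()),
                "hdi_lo": lo, "hdi_hi": hi}

    for k in range(K):
        sp = samples.species_labels[k]
        rows.append(summarize(sp, "psi", inv_logit(lpsi[:, k])))
        rows.append(summarize(sp, "theta", inv_logit(ltheta[:, k])))
        rows.append(summarize(sp, "p", inv_logit(lp[:, k])))
    for fam, kind in (("mu_lpsi", "community_psi"), ("mu_ltheta", "community_theta"),
                      ("mu_lp", "community_p")):
        mu = samples.stacked(fam).reshape(samples.n_total_draws, -1)
        glabels = samples.group_labels or ["community"]
        for g in range(mu.shape[1]):
            rows.append(summarize(glabels[g % len(glabels)], kind, inv_logit(mu[:, g])))
    df = pd.DataFrame(rows, columns=["label", "kind", "mean", "hdi_lo", "hdi_hi"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_truth_record(truth: dict, path):
    """Truth record from the simulator as JSON (arrays listified)."""
    import json

    def enc(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if hasattr(obj, "__dict__"):
            return {k: enc(v) for k, v in vars(obj).items()}
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, default=enc)


__all__ = [
    "read_detection_table",
    "write_detection_table",
    "read_covariates",
    "write_covariates",
    "read_group_table",
    "filter_groups_min_species",
    "write_posterior_summary",
    "write_truth_record",
]
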