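"""Phenotype preparation and variant QC.

Traits are adjusted for fixed-effect covariates (sex, age and batch
factors such as plate, column, machine, part), the residuals are mapped
to standard-normal Z-scores by a rank-based inverse-normal transform,
and variants are filtered on minor allele frequency and imputation
quality before any association testing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .types import DosagePanel, PhenotypePanel, ValidationError


@dataclasses.dataclass
class AdjustedPhenotypes:
    """Covariate-adjusted, inverse-normal transformed traits (Z-scores)."""

    values: pd.DataFrame
    covariates_removed: list[str]
    inverse_normal: bool


def _design_matrix(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariates + one-hot expanded categoricals."""
    cols = [np.ones(0)]
    if covariates is None or covariates.shape[1] == 0:
        return None, ["intercept"]
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for name in covariates.columns:
        col = covariates[name]
        if col.nunique(dropna=True) < 2:
            raise ValidationError(
                f"covariate design is rank-deficient; collinear columns: "
                f"['{name}'] (constant alongside the intercept)"
            )
        if pd.api.types.is_numeric_dtype(col) and col.nunique(dropna=True) > 2:
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
            for d in dummies.columns:
                parts.append(dummies[d].astype(float).rename(d))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(float), list(X.columns)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    bad = [names[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValidationError(
            f"covariate design is rank-deficient; collinear columns: {bad}"
        )


def adjust_covariates(
    traits: pd.DataFrame, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    """OLS residuals of each trait on intercept + covariates.

    With no covariates this reduces to centering. Rows with a missing
    trait or covariate value get a missing residual; each trait is fit on
    its own complete cases.
    """
    if covariates is None or covariates.shape[1] == 0:
        return traits - traits.mean()
    X, names = _design_matrix(covariates)
    cov_ok = ~np.isnan(X).any(axis=1)
    _check_full_rank(X[cov_ok], names)
    out = {}
    for t in traits.columns:
        y = traits[t].to_numpy(float)
        ok = cov_ok & ~np.isnan(y)
        res = np.full(len(y), np.nan)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        res[ok] = y[ok] - X[ok] @ beta
        out[t] = res
    return pd.DataFrame(out, index=traits.index)


def inverse_normal(x) -> np.ndarray:
    """Rank-based inverse-Gaussian transform, offset (rank - 0.5)/n.

    Ties get average ranks; missing values stay missing. Requires at
    least three distinct non-missing values.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 3:
        raise ValidationError(f"inverse_normal needs >= 3 non-missing values, got {n}")
    vals = x[ok]
    if np.all(vals == vals[0]):
        raise ValidationError("inverse_normal undefined for an all-equal input")
    ranks = stats.rankdata(vals, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def prepare(
    panel: PhenotypePanel, covariate_names: list[str] | None = None
) -> AdjustedPhenotypes:
    """Full chain: covariate adjustment, then inverse-normal Z-scores.

    Each resulting column is rescaled to exactly unit sample variance so
    downstream code can rely on Z-scored traits.
    """
    if covariate_names is None:
        covariates = panel.covariates
    elif len(covariate_names) == 0:
        covariates = None
    else:
        if panel.covariates is None:
            raise ValidationError("panel carries no covariates")
        missing = [c for c in covariate_names if c not in panel.covariates.columns]
        if missing:
            raise ValidationError(f"unknown covariates: {missing}")
        covariates = panel.covariates[list(covariate_names)]
    residuals = adjust_covariates(panel.traits, covariates)
    out = {}
    for t in residuals.columns:
        z = inverse_normal(residuals[t].to_numpy())
        sd = np.nanstd(z, ddof=1)
        out[t] = z / sd
    removed = [] if covariates is None else list(covariates.columns)
    return AdjustedPhenotypes(
        values=pd.DataFrame(out, index=residuals.index),
        covariates_removed=removed,
        inverse_normal=True,
    )


def filter_variants(
    panel: DosagePanel, maf_min: float = 0.05, info_min: float = 0.30
) -> tuple[DosagePanel, dict]:
    """Drop variants with MAF < ``maf_min`` or imputation R² < ``info_min``.

    Variants without an info score (directly genotyped) pass the info
    filter. Returns the surviving panel and a QC report with per-criterion
    exclusion counts.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValidationError(f"maf_min must be in [0, 0.5], got {maf_min}")
    maf = panel.maf()
    info = panel.variants["info_score"].to_numpy(float)
    fail_maf = maf < maf_min
    fail_info = ~np.isnan(info) & (info < info_min)
    keep = ~(fail_maf | fail_info)
    report = {
        "n_input": panel.m,
        "n_fail_maf": int(fail_maf.sum()),
        "n_fail_info": int(fail_info.sum()),
        "n_pass": int(keep.sum()),
        "maf_min": maf_min,
        "info_min": info_min,
    }
    return panel.subset_variants(keep), report


def qc_report_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame([report])
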