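"""Score-based replication of multivariate associations.

In the discovery cohort the top variant's dosage is regressed on the
trait group; the fitted coefficients alpha define a compound phenotype
(score) S = Y alpha. In a replication cohort the same score — built
with the *discovery* coefficients — is regressed on the same variant's
dosage, giving the effect beta_S, its standard error and P_S. A locus
replicates when P_S clears the Bonferroni threshold AND beta_S > 0 with
the same effect allele (significance plus directional consistency).

The per-trait partial correlations between dosage and each phenotype
(conditional on the others) form a pleiotropy profile; the Pearson
correlation r_rho between the z-standardized discovery and replication
profiles measures whether the same multivariate effect model holds in
both cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


@dataclasses.dataclass
class ScoreModel:
    """Score coefficients estimated in a discovery cohort."""

    variant_id: str
    effect_allele: str
    trait_names: list[str]
    alpha: np.ndarray
    cohort: str = "discovery"
    n: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.alpha) != len(self.trait_names):
            raise ValidationError("alpha length does not match trait names")
        if not np.any(self.alpha != 0):
            raise ValidationError("score coefficients are all zero")

    def to_json(self, path=None) -> str:
        obj = {
            "variant_id": self.variant_id,
            "effect_allele": self.effect_allele,
            "trait_names": self.trait_names,
            "alpha": self.alpha.tolist(),
            "cohort": self.cohort,
            "n": self.n,
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            variant_id=obj["variant_id"],
            effect_allele=obj["effect_allele"],
            trait_names=list(obj["trait_names"]),
            alpha=np.asarray(obj["alpha"], dtype=float),
            cohort=obj.get("cohort", "discovery"),
            n=int(obj.get("n", 0)),
        )


@dataclasses.dataclass
class PartialCorrelationProfile:
    variant_id: str
    trait_names: list[str]
    rho: np.ndarray
    se: np.ndarray
    z: np.ndarray  # profile standardized to mean 0, sd 1 across traits

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValidationError("partial correlations must lie in [-1, 1]")


@dataclasses.dataclass
class ReplicationRecord:
    variant_id: str
    beta_s: float
    se_s: float
    p_s: float
    r2: float
    n: int
    cohort: str = ""


def _aligned(Y: pd.DataFrame, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Ym = Y.to_numpy(float)
    g = np.asarray(g, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(Ym).any(axis=1)
    return Ym[ok], g[ok]


def estimate_score(
    Y: pd.DataFrame,
    g: np.ndarray,
    variant_id: str = "",
    effect_allele: str = "",
    cohort: str = "discovery",
) -> ScoreModel:
    """OLS coefficients of the dosage on the (centered) traits.

    The F-test of this multiple regression is the MANOVA test of the same
    variant; the coefficients are kept as the score weights.
    """
    Ym, gv = _aligned(Y, g)
    n, k = Ym.shape
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    Yc = Ym - Ym.mean(axis=0)
    gc = gv - gv.mean()
    s = np.linalg.svd(Yc, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > 1e10:
        raise ValidationError("collinear trait columns; reduce the group first")
    alpha, *_ = np.linalg.lstsq(Yc, gc, rcond=None)
    return ScoreModel(
        variant_id=variant_id,
        effect_allele=effect_allele,
        trait_names=list(Y.columns),
        alpha=alpha,
        cohort=cohort,
        n=n,
    )


def score_and_test(
    model: ScoreModel,
    Y_rep: pd.DataFrame,
    g_rep: np.ndarray,
    effect_allele_rep: str | None = None,
    cohort: str = "replication",
) -> ReplicationRecord:
    """Build S = Y alpha with discovery coefficients and regress it on g.

    If the replication file codes the other allele, the dosage is flipped
    (d -> 2 - d); the score itself is never altered. P_S is two-sided; the
    replication verdict additionally requires beta_S > 0.
    """
    missing = [t for t in model.trait_names if t not in Y_rep.columns]
    if missing:
        raise ValidationError(f"replication cohort lacks traits: {missing}")
    g_rep = np.asarray(g_rep, dtype=float)
    if effect_allele_rep is not None and effect_allele_rep != model.effect_allele:
        g_rep = 2.0 - g_rep
    Ym, gv = _aligned(Y_rep[model.trait_names], g_rep)
    n = len(gv)
    if n <= 2:
        raise ValidationError("too few complete samples for the score test")
    S = Ym @ model.alpha
    gc = gv - gv.mean()
    Sc = S - S.mean()
    ss_g = float(gc @ gc)
    if ss_g <= 0:
        raise ValidationError("monomorphic genotype in replication cohort")
    beta = float(gc @ Sc) / ss_g
    resid = Sc - beta * gc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 / ss_g))
    t = beta / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df))
    ss_s = float(Sc @ Sc)
    r2 = (beta * beta * ss_g / ss_s) if ss_s > 0 else 0.0
    return ReplicationRecord(
        variant_id=model.variant_id,
        beta_s=beta,
        se_s=se,
        p_s=min(max(p, 5e-324), 1.0),
        r2=r2,
        n=n,
        cohort=cohort,
    )


def partial_profile(
    Y: pd.DataFrame, g: np.ndarray, variant_id: str = ""
) -> PartialCorrelationProfile:
    """Per-trait partial correlations between dosage and each phenotype.

    rho_j = t_j / sqrt(t_j^2 + df), where t_j is the j-th coefficient's
    t-statistic from the multiple regression of g on Y and df = n - k - 1.
    The z-profile standardizes rho across the k traits (mean 0, sd 1).
    """
    Ym, gv = _aligned(Y, g)
    n, k = Ym.shape
    df = n - k - 1
    if df <= 0:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    if k < 3:
        warnings.warn("fewer than 3 traits: downstream profile consistency is undefined")
    X = np.column_stack([np.ones(n), Ym])
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ gv)
    resid = gv - X @ coef
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se_coef = np.sqrt(np.diag(cov))[1:]
    t = coef[1:] / se_coef
    rho = t / np.sqrt(t * t + df)
    se_rho = np.sqrt((1.0 - rho * rho) / df)
    sd = rho.std(ddof=1) if k > 1 else np.nan
    z = (rho - rho.mean()) / sd if k > 1 and sd > 0 else np.full(k, np.nan)
    return PartialCorrelationProfile(
        variant_id=variant_id,
        trait_names=list(Y.columns),
        rho=rho,
        se=se_rho,
        z=z,
    )


def profile_consistency(
    disc: PartialCorrelationProfile, rep: PartialCorrelationProfile
) -> tuple[float, float]:
    """Cross-cohort consistency r_rho of two pleiotropy profiles.

    Pearson correlation of the z-standardized profiles; the one-sided
    p-value for r > 0 uses t = r sqrt((k-2)/(1-r^2)) with k - 2 df,
    treating the k traits as independent observations (an approximation).
    """
    if disc.trait_names != rep.trait_names:
        raise ValidationError("profiles cover different ordered trait lists")
    k = len(disc.trait_names)
    if k < 3:
        raise ValidationError("profile consistency needs at least 3 traits")
    r = float(np.corrcoef(disc.z, rep.z)[0, 1])
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * np.sqrt((k - 2) / (1.0 - r * r))
        p = float(stats.t.sf(t, k - 2))
    return r, p


def meta_analyze(records) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling of (beta, se) pairs."""
    pairs = [(r.beta_s, r.se_s) if isinstance(r, ReplicationRecord) else tuple(r) for r in records]
    if len(pairs) < 1:
        raise ValidationError("meta-analysis needs at least one record")
    betas = np.array([b for b, _ in pairs], dtype=float)
    ses = np.array([s for _, s in pairs], dtype=float)
    if np.any(ses <= 0):
        raise ValidationError("standard errors must be positive")
    w = 1.0 / (ses * ses)
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, min(max(p, 5e-324), 1.0)
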