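"""Per-variant multivariate association test (Pillai's trace MANOVA).

For k phenotypes Y (n x k) and one biallelic dosage vector g, the
multivariate regression Y = 1 mu' + g beta' + e is tested for H0:
beta = 0. With E the residual cross-product matrix of the full model,
E0 that of the intercept-only model, and H = E0 - E, Pillai's trace is

    V = tr(H (H + E)^{-1}) = sum_j lambda_j / (1 + lambda_j)

over the eigenvalues of det(H - lambda E) = 0. For a single predictor
H has rank one, and V equals the R^2 of the reverse regression of g on
Y — the fast path used for genome scans. The F-statistic

    F = (V / k) / ((1 - V) / (n - k - 1)) ~ F_{k, n-k-1}

gives the p-value; k*F is approximately chi^2(k) for large n.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .types import DosagePanel, ScanOutput, ValidationError

_V_MAX = 1.0 - 1e-15
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45493642...


@dataclasses.dataclass
class ManovaResult:
    variant_id: str
    V: float
    F: float
    df1: int
    df2: int
    p: float
    n_used: int
    k: int
    monomorphic: bool = False


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def _complete_case(Y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(g) & ~np.isnan(Y).any(axis=1)
    return Y[ok], g[ok]


def drop_collinear(Y: np.ndarray, cond_max: float = 1e10) -> np.ndarray:
    """Indices of a maximal well-conditioned subset of (centered) columns."""
    Yc = Y - Y.mean(axis=0)
    keep: list[int] = []
    for j in range(Yc.shape[1]):
        cand = keep + [j]
        s = np.linalg.svd(Yc[:, cand], compute_uv=False)
        if s[-1] <= 0 or s[0] / s[-1] > cond_max:
            continue
        keep.append(j)
    return np.array(keep, dtype=int)


def reverse_regression_r2(Y: np.ndarray, g: np.ndarray) -> float:
    """R^2 of the multiple regression of centered g on centered Y."""
    Y, g = _complete_case(np.asarray(Y, float), np.asarray(g, float))
    n, k = Y.shape
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    gc = g - g.mean()
    ss_g = float(gc @ gc)
    if ss_g <= 0:
        raise ValidationError("monomorphic genotype vector")
    Yc = Y - Y.mean(axis=0)
    s = np.linalg.svd(Yc, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > 1e10:
        raise ValidationError(
            "phenotype columns are collinear within this group; "
            "drop redundant traits (see drop_collinear)"
        )
    Q, _ = np.linalg.qr(Yc)
    proj = Q.T @ gc
    r2 = float(proj @ proj) / ss_g
    return min(max(r2, 0.0), _V_MAX)


def f_and_chi2_p(V: float, k: int, n: int) -> tuple[float, float, float]:
    """F statistic and its exact-F and chi^2(k) approximation p-values."""
    if not (0.0 <= V < 1.0):
        raise ValidationError(f"Pillai V must be in [0, 1), got {V}")
    df2 = n - k - 1
    if df2 <= 0:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    F = (V / k) / ((1.0 - V) / df2)
    p_f = float(stats.f.sf(F, k, df2))
    p_chi2 = float(stats.chi2.sf(k * F, k))
    return float(F), min(max(p_f, 5e-324), 1.0), min(max(p_chi2, 5e-324), 1.0)


def pillai_manova(Y, g, variant_id: str = "") -> ManovaResult:
    """Pillai-trace MANOVA of one variant against a trait matrix.

    Uses the reverse-regression shortcut (V = R^2 of g on Y); the explicit
    E/E0/H eigen-solve is available as :func:`pillai_eigen` for
    verification. A monomorphic variant yields a flagged result with a
    missing p-value rather than an error.
    """
    Y = np.asarray(Y, float)
    g = np.asarray(g, float)
    Yc, gc = _complete_case(Y, g)
    n, k = Yc.shape
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    if np.ptp(gc) == 0:
        return ManovaResult(
            variant_id=variant_id, V=np.nan, F=np.nan, df1=k, df2=n - k - 1,
            p=np.nan, n_used=n, k=k, monomorphic=True,
        )
    V = reverse_regression_r2(Yc, gc)
    F, p_f, _ = f_and_chi2_p(V, k, n)
    return ManovaResult(
        variant_id=variant_id, V=V, F=F, df1=k, df2=n - k - 1, p=p_f,
        n_used=n, k=k,
    )


def pillai_eigen(Y, g) -> float:
    """Pillai's trace via the explicit E / E0 / H generalized eigenproblem.

    Independent formulation kept as the verification oracle for
    :func:`reverse_regression_r2`; O(k^3) per variant, so not used in scans.
    """
    Y, g = _complete_case(np.asarray(Y, float), np.asarray(g, float))
    n, k = Y.shape
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    E = resid.T @ resid
    Y0 = Y - Y.mean(axis=0)
    E0 = Y0.T @ Y0
    H = E0 - E
    lam = linalg.eigvals(H, E)
    lam = np.real(lam[np.abs(np.imag(lam)) < 1e-8])
    lam = np.clip(lam, 0.0, None)
    return float(np.sum(lam / (1.0 + lam)))


def manova_statistics(Y, g) -> pd.DataFrame:
    """Pillai, Wilks, Hotelling-Lawley and Roy statistics for one variant.

    For a single-predictor test all four are one-to-one functions of the
    single nonzero eigenvalue, and their exact F-tests coincide.
    """
    Y, g = _complete_case(np.asarray(Y, float), np.asarray(g, float))
    n, k = Y.shape
    df2 = n - k - 1
    V = reverse_regression_r2(Y, g)
    lam = V / (1.0 - V)  # the single nonzero eigenvalue of det(H - lam E) = 0
    rows = []
    stats_defs = {
        "pillai": (V, (V / k) / ((1 - V) / df2)),
        "wilks": (1.0 - V, ((1 - (1 - V)) / (1 - V)) * (df2 / k)),
        "hotelling-lawley": (lam, lam * df2 / k),
        "roy": (lam, lam * df2 / k),
    }
    for name, (stat, F) in stats_defs.items():
        rows.append(
            {"statistic": name, "value": stat, "F": F,
             "p": float(stats.f.sf(F, k, df2))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def scan(
    traits: pd.DataFrame,
    panel: DosagePanel,
    group: list[str] | None = None,
    group_name: str = "all",
    cond_max: float = 1e10,
) -> tuple[ScanOutput, dict]:
    """MANOVA of every panel variant against one trait group.

    Complete-data panels use a fully vectorized path (one QR of the trait
    matrix, one matrix product for all variants); variants with missing
    dosages fall back to a per-variant complete-case computation. Returns
    the per-variant table and a summary with the genomic-control lambda.
    """
    if group is None:
        group = list(traits.columns)
    if len(group) == 0:
        raise ValidationError("empty trait group")
    missing_traits = [t for t in group if t not in traits.columns]
    if missing_traits:
        raise ValidationError(f"group references unknown traits: {missing_traits}")
    Y = traits[list(group)].to_numpy(float)
    row_ok = ~np.isnan(Y).any(axis=1)
    Yr = Y[row_ok]
    keep = drop_collinear(Yr, cond_max)
    if len(keep) < Y.shape[1]:
        dropped = [group[j] for j in range(len(group)) if j not in set(keep.tolist())]
        warnings.warn(
            f"group {group_name!r}: dropping collinear trait(s) {dropped}"
        )
        Y = Y[:, keep]
        group = [group[j] for j in keep]
    k = Y.shape[1]

    G = panel.dosages
    n_total, m = G.shape
    results = np.full((m, 4), np.nan)  # V, F, p, n_used
    mono = np.zeros(m, dtype=bool)

    complete_rows = row_ok & ~np.isnan(G).any(axis=1)
    if complete_rows.sum() == n_total and row_ok.all():
        # fast path: no missingness anywhere
        Yc = Y - Y.mean(axis=0)
        Q, _ = np.linalg.qr(Yc)
        Gc = G - G.mean(axis=0)
        ss_g = np.einsum("ij,ij->j", Gc, Gc)
        proj = Q.T @ Gc
        num = np.einsum("ij,ij->j", proj, proj)
        mono = ss_g <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            V = np.where(mono, np.nan, num / np.where(ss_g > 0, ss_g, 1.0))
        V = np.clip(V, 0.0, _V_MAX)
        df2 = n_total - k - 1
        if df2 <= 0:
            raise ValidationError(f"need n > k + 1 (n={n_total}, k={k})")
        F = (V / k) / ((1.0 - V) / df2)
        p = stats.f.sf(F, k, df2)
        results[:, 0], results[:, 1], results[:, 2] = V, F, np.clip(p, 5e-324, 1.0)
        results[:, 3] = n_total
        results[mono, :3] = np.nan
    else:
        for j in range(m):
            r = pillai_manova(Y, G[:, j], variant_id=str(panel.variants["variant_id"].iloc[j]))
            mono[j] = r.monomorphic
            results[j] = (r.V, r.F, r.p, r.n_used)

    table = panel.variants[["variant_id", "chrom", "pos", "effect_allele"]].copy()
    table["maf"] = panel.maf()
    table["n_used"] = results[:, 3].astype(int)
    table["k"] = k
    table["V"] = results[:, 0]
    table["F"] = results[:, 1]
    table["p_manova"] = results[:, 2]

    p_ok = results[~mono, 2]
    p_ok = p_ok[~np.isnan(p_ok)]
    lam = genomic_lambda(p_ok) if len(p_ok) else np.nan
    metadata = {
        "trait_group": group_name,
        "k": k,
        "n_variants": m,
        "lambda": lam,
    }
    summary = dict(metadata)
    summary["n_monomorphic"] = int(mono.sum())
    return ScanOutput(table=table, metadata=metadata), summary


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor from a set of p-values.

    Each p-value is converted to its 1-df chi-square equivalent so that
    lambda is comparable across trait-group sizes; lambda is the median of
    those statistics over the null median 0.4549.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if len(p) < 100:
        warnings.warn(f"genomic lambda from only {len(p)} p-values is unstable")
    chi1 = stats.chi2.isf(p, 1)
    return float(np.median(chi1) / _CHI2_1_MEDIAN)


def significance_thresholds(
    alpha_gw: float = 5e-8, n_scans: int = 9, n_loci: int = 5
) -> tuple[float, float]:
    """Bonferroni thresholds for discovery and replication.

    discovery = alpha_gw / n_scans (e.g. 5e-8 / 9 = 5.6e-9);
    replication = 0.05 / (n_loci * n_scans) (e.g. 0.05 / 5 / 9 = 1.1e-3).
    """
    if n_scans < 1 or n_loci < 1:
        raise ValidationError("n_scans and n_loci must be positive integers")
    return alpha_gw / n_scans, 0.05 / (n_loci * n_scans)
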