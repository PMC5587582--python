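"""Baseline single-trait methods for power comparisons.

Two comparators for the multivariate scan: per-trait univariate OLS
GWAS (with genomic control), and a TATES-style combination that adjusts
the smallest univariate p-value by a Li-Ji eigenvalue estimate of the
effective number of correlated tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import DosagePanel, ValidationError
from .manova import genomic_lambda


def univariate_scan(
    traits: pd.DataFrame, panel: DosagePanel
) -> tuple[pd.DataFrame, dict[str, float]]:
    """OLS slope test of every variant against every trait.

    Returns a long table (variant x trait: beta, se, t, p) and the
    per-trait genomic-control lambda. Missing dosages are handled
    pairwise-complete via count/sum accumulation.
    """
    G = panel.dosages
    n, m = G.shape
    obs = ~np.isnan(G)
    Gf = np.where(obs, G, 0.0)
    frames = []
    lambdas: dict[str, float] = {}
    for trait in traits.columns:
        y = traits[trait].to_numpy(float)
        ok_y = ~np.isnan(y)
        M = obs & ok_y[:, None]
        yf = np.where(ok_y, y, 0.0)
        nv = M.sum(axis=0).astype(float)
        Sg = (Gf * ok_y[:, None]).sum(axis=0)
        Sgg = (Gf * Gf * ok_y[:, None]).sum(axis=0)
        Sy = yf @ obs
        Syy = (yf * yf) @ obs
        Sgy = yf @ Gf
        with np.errstate(invalid="ignore", divide="ignore"):
            var_g = Sgg - Sg * Sg / nv
            var_y = Syy - Sy * Sy / nv
            cov = Sgy - Sg * Sy / nv
            beta = cov / var_g
            df = nv - 2
            sigma2 = (var_y - beta * cov) / df
            se = np.sqrt(sigma2 / var_g)
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": panel.variants["variant_id"].values,
                    "trait": trait,
                    "n_used": nv.astype(int),
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": np.clip(p, 5e-324, 1.0),
                }
            )
        )
        p_ok = frames[-1]["p"].to_numpy()
        p_ok = p_ok[~np.isnan(p_ok)]
        lambdas[trait] = genomic_lambda(p_ok) if len(p_ok) else np.nan
    return pd.concat(frames, ignore_index=True), lambdas


def gc_correct(p_values, lam: float) -> np.ndarray:
    """Genomic-control correction: divide the 1-df chi-square by lambda."""
    p = np.asarray(p_values, dtype=float)
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    chi = stats.chi2.isf(p, 1) / lam
    return stats.chi2.sf(chi, 1)


def effective_tests(R: np.ndarray) -> float:
    """Li-Ji effective number of tests from a correlation matrix.

    m_e = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ] over the
    eigenvalues of R; equals k for independent traits and 1 for perfectly
    correlated ones.
    """
    lam = np.linalg.eigvalsh(np.asarray(R, float))
    # round before floor(): floating noise at integer eigenvalues (e.g. an
    # all-ones matrix) would otherwise flip the fractional part from 0 to ~1
    lam = np.round(np.clip(lam, 0.0, None), 9)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def tates_combine(p_values, R) -> float:
    """TATES-style adjusted minimum p-value.

    Sort the k univariate p-values ascending; for each prefix of j traits
    compute the effective number of tests m_e(j) from the corresponding
    correlation submatrix, and return min_j { m_e(k)/m_e(j) * p_(j) },
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    R = np.asarray(R, dtype=float)
    k = len(p)
    if R.shape != (k, k):
        raise ValidationError(f"correlation matrix shape {R.shape} does not match k={k}")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(np.linalg.eigvalsh(R) < -1e-8):
        raise ValidationError("trait correlation matrix must be positive semidefinite")
    order = np.argsort(p)
    p_sorted = p[order]
    me_total = effective_tests(R)
    best = np.inf
    for j in range(1, k + 1):
        sub = R[np.ix_(order[:j], order[:j])]
        me_j = effective_tests(sub)
        best = min(best, me_total / me_j * p_sorted[j - 1])
    return float(min(best, 1.0))
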