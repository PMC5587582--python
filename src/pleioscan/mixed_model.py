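"""Polygenic linear mixed model and the GRAMMAR+ phenotype transformation.

Each trait y is modelled as

    y ~ N(mu 1, sigma^2 * (h2 K + (1 - h2) I))

with K a genomic relationship matrix. The heritability h2 is estimated
by REML via a one-dimensional bounded optimization after a single
eigendecomposition of K, so fitting k traits costs one decomposition
plus k cheap scalar searches.

The GRAMMAR+ transformation whitens each trait with the fitted
polygenic covariance,

    c * V^{-1/2} (y - mu 1),   V = h2 K + (1 - h2) I,
    c = 1 / mean(diag(V^{-1/2})),

recentred to mean zero. Under the null the whitened trait has i.i.d.
entries independent of any genotype, so per-variant ordinary
least-squares tests on the transformed trait are calibrated in
family-structured samples (genomic-control lambda near 1). That
calibration is the transformation's contract and is what the test suite
verifies; plain V^{-1} residuals are markedly conservative under
strong family structure, which is why the whitening form is used. The
scalar c keeps the output invariant to any constant rescaling of K
(which the variance components absorb).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .types import KinshipMatrix, ValidationError

_H2_HI = 1.0 - 1e-6
_FLAT_TOL = 1e-7


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the likelihood profile for inspection."""

    def __init__(self, message: str, profile=None):
        super().__init__(message)
        self.profile = profile


@dataclasses.dataclass
class VarianceComponents:
    h2: float
    sigma2_g: float
    sigma2_e: float
    loglik: float
    converged: bool
    identifiable: bool = True

    def __post_init__(self) -> None:
        total = self.sigma2_g + self.sigma2_e
        if total > 0 and abs(self.h2 - self.sigma2_g / total) > 1e-8:
            raise ValidationError("h2 inconsistent with variance components")


@dataclasses.dataclass
class TransformedPhenotypes:
    values: pd.DataFrame
    components: dict[str, VarianceComponents]
    kinship: KinshipMatrix


def kinship_eigen(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of K, shared across per-trait fits."""
    d, U = np.linalg.eigh(K.values)
    if d.min() < -1e-8:
        raise ValidationError(
            f"kinship has negative eigenvalue {d.min():.3g}; apply make_psd first"
        )
    return np.clip(d, 0.0, None), U


def _reml_neg_loglik(h2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """-2x restricted log-likelihood (up to a constant), intercept-only fixed effects."""
    n = len(yt)
    w = h2 * d + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf
    xtw = xt * xt / w
    xx = xtw.sum()
    mu = (xt * yt / w).sum() / xx
    r = yt - mu * xt
    q = (r * r / w).sum()
    if q <= 0:
        return np.inf
    return float(np.log(w).sum() + np.log(xx) + (n - 1) * np.log(q))


def _reml_score(h2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """d/dh2 of the -2x restricted log-likelihood (envelope theorem for mu)."""
    n = len(yt)
    w = h2 * d + (1.0 - h2)
    dd = d - 1.0
    sxx = (xt * xt / w).sum()
    mu = (xt * yt / w).sum() / sxx
    r = yt - mu * xt
    q = (r * r / w).sum()
    return float(
        (dd / w).sum()
        - (xt * xt * dd / (w * w)).sum() / sxx
        - (n - 1) * (r * r * dd / (w * w)).sum() / q
    )


def fit_polygenic(
    y: np.ndarray,
    K: KinshipMatrix | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    grid_points: int = 21,
) -> VarianceComponents:
    """REML estimate of h2 for one trait.

    A coarse profile over h2 in [0, 1] brackets the optimum, which is then
    refined by bounded scalar minimization. A flat profile (e.g. K = I,
    where h2 is unidentifiable) is flagged via ``identifiable=False`` and
    reported as h2 = 0.
    """
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = kinship_eigen(K)
    d, U = eig
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValidationError("fit_polygenic requires a complete trait vector")
    n = len(y)
    if n != len(d):
        raise ValidationError("trait length does not match kinship dimension")
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    grid = np.linspace(0.0, _H2_HI, grid_points)
    prof = np.array([_reml_neg_loglik(h, d, yt, xt) for h in grid])
    if not np.isfinite(prof).any():
        raise ConvergenceError("restricted likelihood is not finite anywhere", profile=(grid, prof))
    best = int(np.nanargmin(prof))
    span = float(np.nanmax(prof) - np.nanmin(prof))
    identifiable = span > _FLAT_TOL * max(1.0, abs(float(np.nanmin(prof))))

    if not identifiable:
        h2 = 0.0
    else:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid_points - 1)]
        s_lo, s_hi = _reml_score(lo, d, yt, xt), _reml_score(hi, d, yt, xt)
        if s_lo > 0 and best == 0:
            h2 = 0.0  # boundary optimum at h2 = 0
        elif s_hi < 0 and best == grid_points - 1:
            h2 = _H2_HI  # boundary optimum at h2 -> 1
        elif s_lo * s_hi < 0:
            # machine-precision interior optimum via the analytic score
            h2 = float(
                optimize.brentq(_reml_score, lo, hi, args=(d, yt, xt), xtol=1e-13)
            )
        else:
            res = optimize.minimize_scalar(
                _reml_neg_loglik, bounds=(lo, hi), args=(d, yt, xt), method="bounded",
                options={"xatol": 1e-11, "maxiter": 200},
            )
            if not res.success:
                raise ConvergenceError(
                    f"REML optimizer failed: {res.message}", profile=(grid, prof)
                )
            h2 = float(res.x) if res.fun <= prof[best] else float(grid[best])

    w = h2 * d + (1.0 - h2)
    xx = (xt * xt / w).sum()
    mu = (xt * yt / w).sum() / xx
    r = yt - mu * xt
    sigma2 = float((r * r / w).sum() / (n - 1))
    nll = _reml_neg_loglik(h2, d, yt, xt)
    loglik = -0.5 * (nll + (n - 1) * (1.0 + np.log(2.0 * np.pi / (n - 1))))
    return VarianceComponents(
        h2=h2,
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        loglik=float(loglik),
        converged=True,
        identifiable=bool(identifiable),
    )


def grammar_plus_transform(
    y: np.ndarray,
    K: KinshipMatrix | None,
    vc: VarianceComponents,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """GRAMMAR+ residuals: c * V^{-1/2}(y - mu 1), recentred to mean zero.

    c = 1/mean(diag(V^{-1/2})) restores the trait's scale (and makes the
    output invariant to constant rescaling of K). With h2 = 0 (or K = I)
    the result is exactly the centered trait.
    """
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = kinship_eigen(K)
    d, U = eig
    y = np.asarray(y, dtype=float)
    w = vc.h2 * d + (1.0 - vc.h2)
    if np.any(w <= 1e-12):
        raise ValidationError(
            "V = h2 K + (1-h2) I is numerically singular; repair K with make_psd"
        )
    sqrt_w = np.sqrt(w)
    yt = U.T @ y
    xt = U.T @ np.ones(len(y))
    mu = (xt * yt / w).sum() / (xt * xt / w).sum()
    r_rot = (yt - mu * xt) / sqrt_w
    r = U @ r_rot
    diag_vinvhalf = (U * U) @ (1.0 / sqrt_w)
    c = 1.0 / float(diag_vinvhalf.mean())
    r = c * r
    return r - r.mean()


def transform_panel(
    traits: pd.DataFrame, K: KinshipMatrix, decorrelate: bool = True
) -> TransformedPhenotypes:
    """Fit the polygenic model per trait and GRAMMAR+ transform each column.

    With ``decorrelate=True`` (default) the trait matrix is first rotated
    to its phenotypic principal components, each rotated column is
    whitened with its own univariate polygenic fit, and the result is
    rotated back. The MANOVA scan is invariant to any invertible
    trait-space map, so the rotation changes nothing about the test's
    meaning; it removes cross-trait covariance that per-column whitening
    alone leaves family-structured, which would otherwise inflate joint
    tests under strong relatedness. The reported per-trait variance
    components always come from univariate fits of the original traits.

    Columns with missing values fall back to per-column whitening on
    their complete cases (the rotation needs complete rows).
    """
    eig = kinship_eigen(K)
    comps = {}
    for t in traits.columns:
        y = traits[t].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.all():
            comps[t] = fit_polygenic(y, eig=eig)
        else:
            sub_ids = [s for s, keep in zip(K.sample_ids, ok) if keep]
            eig_sub = kinship_eigen(K.subset_samples(sub_ids))
            comps[t] = fit_polygenic(y[ok], eig=eig_sub)

    Y = traits.to_numpy(float)
    complete = not np.isnan(Y).any()
    if decorrelate and complete and traits.shape[1] > 1:
        Yc = Y - Y.mean(axis=0)
        _, P = np.linalg.eigh(np.cov(Yc, rowvar=False))
        Yr = Yc @ P
        out = np.empty_like(Yr)
        for j in range(Yr.shape[1]):
            vc_j = fit_polygenic(Yr[:, j], eig=eig)
            out[:, j] = grammar_plus_transform(Yr[:, j], None, vc_j, eig=eig)
        values = pd.DataFrame(out @ P.T, columns=traits.columns, index=traits.index)
    else:
        cols = {}
        for t in traits.columns:
            y = traits[t].to_numpy(float)
            ok = ~np.isnan(y)
            if ok.all():
                cols[t] = grammar_plus_transform(y, None, comps[t], eig=eig)
            else:
                sub_ids = [s for s, keep in zip(K.sample_ids, ok) if keep]
                eig_sub = kinship_eigen(K.subset_samples(sub_ids))
                col = np.full(len(y), np.nan)
                col[ok] = grammar_plus_transform(y[ok], None, comps[t], eig=eig_sub)
                cols[t] = col
        values = pd.DataFrame(cols, index=traits.index)
    return TransformedPhenotypes(values=values, components=comps, kinship=K)


def components_frame(comps: dict[str, VarianceComponents]) -> pd.DataFrame:
    """Sidecar table of per-trait variance-component estimates."""
    rows = [
        {
            "trait": t,
            "h2": v.h2,
            "sigma2_g": v.sigma2_g,
            "sigma2_e": v.sigma2_e,
            "loglik": v.loglik,
            "converged": v.converged,
            "identifiable": v.identifiable,
        }
        for t, v in comps.items()
    ]
    return pd.DataFrame(rows)
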