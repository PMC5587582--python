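"""Genomic relationship matrix (GRM) estimation.

The frequency-weighted identity-by-state estimator

    K[i, j] = (1/m) * sum_s (g_is - 2 p_s)(g_js - 2 p_s) / (2 p_s (1 - p_s))

with allele frequencies p_s taken from the sample (VanRaden scaling:
expected diagonal 1 under Hardy-Weinberg equilibrium). Any constant
rescaling of K is absorbed by the mixed model's variance components, so
only the scale-free structure matters downstream.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import DosagePanel, KinshipMatrix, ValidationError


def compute_grm(panel: DosagePanel, min_variance: float = 1e-12) -> KinshipMatrix:
    """Frequency-weighted GRM from a dosage panel.

    Monomorphic variants are excluded with a warning. Missing dosages are
    handled pairwise-complete: a variant contributes to K[i, j] only when
    both dosages are observed, and the sum is divided by the number of
    variants actually used for that pair.
    """
    X = panel.dosages
    if X.shape[1] < 1:
        raise ValidationError("GRM requires at least 1 variant")
    p = panel.allele_freq()
    denom = 2.0 * p * (1.0 - p)
    poly = denom > min_variance
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(f"excluding {n_mono} monomorphic variant(s) from the GRM")
    if poly.sum() < 1:
        raise ValidationError("no polymorphic variants; cannot form a GRM")
    Xp = X[:, poly]
    Z = (Xp - 2.0 * p[poly]) / np.sqrt(denom[poly])
    obs = ~np.isnan(Z)
    Zf = np.where(obs, Z, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    if np.any(counts == 0):
        raise ValidationError("a sample pair shares no observed variants")
    K = (Zf @ Zf.T) / counts
    K = 0.5 * (K + K.T)
    return KinshipMatrix(
        values=K,
        sample_ids=list(panel.sample_ids),
        estimator="freq-weighted-ibs",
        n_variants=int(poly.sum()),
    )


def make_psd(K: KinshipMatrix, epsilon: float = 1e-6) -> tuple[KinshipMatrix, dict]:
    """Clip negative eigenvalues to ``epsilon``; report what changed."""
    w, U = np.linalg.eigh(K.values)
    neg = w < 0
    n_clipped = int(neg.sum())
    if n_clipped == 0:
        return K, {"n_clipped": 0, "max_change": 0.0}
    w_fixed = np.where(neg, epsilon, w)
    V = (U * w_fixed) @ U.T
    V = 0.5 * (V + V.T)
    report = {
        "n_clipped": n_clipped,
        "max_change": float(np.max(np.abs(V - K.values))),
    }
    out = KinshipMatrix(
        values=V,
        sample_ids=list(K.sample_ids),
        estimator=K.estimator + "+psd",
        n_variants=K.n_variants,
    )
    return out, report
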