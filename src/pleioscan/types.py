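"""Core data containers shared across the package.

The three on-disk artifacts of a multivariate GWAS — genotype dosages,
phenotypes with covariates and trait groups, and a genomic relationship
matrix — are represented by small validated containers built on pandas /
numpy. All downstream modules operate on these, aligned to a common
sample order (see :func:`align_samples`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a container invariant."""


class ParseError(ValueError):
    """A file could not be interpreted in its declared format."""


#: canonical per-variant metadata columns, in order
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "info_score",
]


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclasses.dataclass
class DosagePanel:
    """n samples x m variants of expected allele counts in [0, 2].

    Dosages are oriented to the stated effect allele; missing entries are
    NaN (never silently zeroed). ``info_score`` is the imputation R² in
    [0, 1], NaN for directly genotyped markers.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.dosages = _as_float_matrix(self.dosages, "dosages")
        if list(self.variants.columns[: len(VARIANT_COLUMNS)]) != VARIANT_COLUMNS:
            missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
            if missing:
                raise ValidationError(f"variant table missing columns {missing}")
            self.variants = self.variants[VARIANT_COLUMNS].copy()
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"dosage rows ({n}) != number of sample ids ({len(self.sample_ids)})"
            )
        if m != len(self.variants):
            raise ValidationError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            dupes = vid[vid.duplicated()].unique()[:5].tolist()
            raise ValidationError(f"duplicate variant ids: {dupes}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage outside [0, 2]: value {self.dosages[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, variant {vid.iloc[j]!r}"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per variant from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask_or_idx) -> "DosagePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return DosagePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, ids: Sequence[str]) -> "DosagePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[str(s)] for s in ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None
        return DosagePanel(
            sample_ids=[str(s) for s in ids],
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :],
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero((self.variants["variant_id"] == variant_id).values)
        if len(hits) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(hits[0])


@dataclasses.dataclass
class PhenotypePanel:
    """n samples x k traits, plus covariates and named trait groups.

    ``trait_groups`` maps a group name to an ordered subset of trait
    names; the implicit group ``"all"`` (every trait) is always present.
    """

    sample_ids: list[str]
    traits: pd.DataFrame
    covariates: pd.DataFrame | None = None
    trait_groups: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if len(self.traits) != n:
            raise ValidationError("trait rows do not match sample ids")
        if self.traits.shape[1] < 1:
            raise ValidationError("at least one trait is required")
        if self.traits.columns.duplicated().any():
            raise ValidationError("trait names are not unique")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariate rows do not match sample ids")
        known = set(self.traits.columns)
        groups = {"all": list(self.traits.columns)}
        for name, members in self.trait_groups.items():
            unknown = [t for t in members if t not in known]
            if unknown:
                raise ValidationError(
                    f"trait group {name!r} references unknown traits: {unknown}"
                )
            groups[name] = list(members)
        self.trait_groups = groups
        self.traits = self.traits.reset_index(drop=True)
        if self.covariates is not None:
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return self.traits.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "PhenotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[str(s)] for s in ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None
        groups = {k: v for k, v in self.trait_groups.items() if k != "all"}
        return PhenotypePanel(
            sample_ids=[str(s) for s in ids],
            traits=self.traits.iloc[rows].reset_index(drop=True),
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[rows].reset_index(drop=True),
            trait_groups=groups,
        )


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric n x n genomic relationship matrix (VanRaden scaling, diag ~ 1)."""

    values: np.ndarray
    sample_ids: list[str]
    estimator: str = "freq-weighted-ibs"
    n_variants: int | None = None

    SYMMETRY_TOL = 1e-8

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = _as_float_matrix(self.values, "kinship")
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kinship shape {self.values.shape} does not match {n} sample ids"
            )
        asym = float(np.max(np.abs(self.values - self.values.T))) if n else 0.0
        if asym > self.SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.argmax(np.abs(self.values - self.values.T)), self.values.shape
            )
            raise ValidationError(
                f"kinship not symmetric: |K[{i},{j}] - K[{j},{i}]| = {asym:.3g}"
            )
        # exact symmetry downstream (eigendecompositions assume it)
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = np.array([pos[str(s)] for s in ids])
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None
        return KinshipMatrix(
            values=self.values[np.ix_(rows, rows)],
            sample_ids=[str(s) for s in ids],
            estimator=self.estimator,
            n_variants=self.n_variants,
        )


@dataclasses.dataclass
class ScanOutput:
    """Serialized result of one MANOVA scan: per-variant table + header metadata."""

    table: pd.DataFrame
    metadata: dict

    def __post_init__(self) -> None:
        if "p_manova" in self.table.columns:
            p = self.table["p_manova"].to_numpy(dtype=float)
            ok = np.isnan(p) | ((p > 0) & (p <= 1))
            if not ok.all():
                raise ValidationError("p_manova values must lie in (0, 1]")


def align_samples(
    dosages: DosagePanel,
    phenotypes: PhenotypePanel,
    kinship: KinshipMatrix | None = None,
    min_overlap: float = 0.9,
):
    """Restrict all inputs to their common samples, in dosage-file order.

    Raises :class:`ValidationError` when the intersection covers less than
    ``min_overlap`` of any input's samples, so silent sample loss cannot
    go unnoticed.
    """
    sets = [set(dosages.sample_ids), set(phenotypes.sample_ids)]
    if kinship is not None:
        sets.append(set(kinship.sample_ids))
    common = set.intersection(*sets)
    ordered = [s for s in dosages.sample_ids if s in common]
    if not ordered:
        raise ValidationError("no samples shared between inputs")
    for label, ids in zip(
        ("dosage", "phenotype", "kinship"), sets
    ):
        frac = len(common) / len(ids)
        if frac < min_overlap:
            raise ValidationError(
                f"sample overlap covers only {frac:.1%} of the {label} input "
                f"(minimum {min_overlap:.0%}); refusing to drop samples silently"
            )
    out = [dosages.subset_samples(ordered), phenotypes.subset_samples(ordered)]
    if kinship is not None:
        out.append(kinship.subset_samples(ordered))
    return tuple(out)
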