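"""Readers and writers for on-disk artifacts.

Formats
-------
dosage TSV
    Wide matrix: first column ``variant`` holds the metadata key
    ``variant_id:chrom:pos:EA:OA:info`` (``info`` may be ``NA``); the
    remaining columns are samples; entries are dosages in [0, 2] or
    ``NA``.
VCF
    Any uncompressed or bgzipped VCF with a per-genotype dosage FORMAT
    field (default ``DS``); imputation R² is taken from the first of the
    INFO keys ``INFO``, ``R2``, ``DR2`` present.
phenotype TSV
    Header row; one sample-id column; covariates named at read time;
    every other numeric column is a trait.
trait-group TSV
    ``group_name<TAB>trait1,trait2,...`` per line.
kinship
    Either a square TSV (ids as header and first column) or a GCTA-style
    text pair ``<prefix>.grm`` (1-based i, j, n_variants, value over the
    lower triangle) + ``<prefix>.grm.id``.
scan TSV
    ``#key=value`` header lines followed by a TSV table; numeric columns
    round-trip losslessly (17 significant digits).
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    VARIANT_COLUMNS,
    DosagePanel,
    KinshipMatrix,
    ParseError,
    PhenotypePanel,
    ScanOutput,
    ValidationError,
)

_NA_STRINGS = {"", "NA", "nan", "NaN", "."}


def _parse_float(token: str, path, lineno: int) -> float:
    if token in _NA_STRINGS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: cannot parse {token!r} as a number") from None


# ---------------------------------------------------------------------------
# dosages
# ---------------------------------------------------------------------------

def variant_key(row) -> str:
    info = row["info_score"]
    info_s = "NA" if (info is None or (isinstance(info, float) and math.isnan(info))) else f"{info:.6g}"
    return ":".join(
        [
            str(row["variant_id"]),
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["effect_allele"]),
            str(row["other_allele"]),
            info_s,
        ]
    )


def _parse_variant_key(key: str, path, lineno: int) -> dict:
    parts = key.split(":")
    if len(parts) != 6:
        raise ParseError(
            f"{path}:{lineno}: variant key {key!r} must have 6 ':'-separated fields "
            "(variant_id:chrom:pos:EA:OA:info)"
        )
    vid, chrom, pos, ea, oa, info = parts
    try:
        pos_i = int(pos)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: position {pos!r} is not an integer") from None
    return {
        "variant_id": vid,
        "chrom": chrom,
        "pos": pos_i,
        "effect_allele": ea,
        "other_allele": oa,
        "info_score": _parse_float(info, path, lineno),
    }


def read_dosages(path, format: str = "tsv", dosage_field: str = "DS") -> DosagePanel:
    """Read a genotype dosage panel from ``tsv`` or ``vcf-dosage`` format."""
    if format == "tsv":
        return _read_dosages_tsv(path)
    if format == "vcf-dosage":
        return _read_dosages_vcf(path, dosage_field=dosage_field)
    raise ValueError(f"unknown dosage format {format!r}")


def _read_dosages_tsv(path) -> DosagePanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected a variant column plus sample columns")
        sample_ids = header[1:]
        records, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            records.append(_parse_variant_key(fields[0], path, lineno))
            rows.append([_parse_float(t, path, lineno) for t in fields[1:]])
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return DosagePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


def write_dosages(panel: DosagePanel, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("variant\t" + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.m):
            key = variant_key(panel.variants.iloc[j])
            col = panel.dosages[:, j]
            vals = "\t".join("NA" if math.isnan(v) else f"{v:.17g}" for v in col)
            fh.write(f"{key}\t{vals}\n")


def _read_dosages_vcf(path, dosage_field: str = "DS") -> DosagePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records, cols = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: variant {var.ID or var.POS} is multi-allelic; split upstream"
            )
        ds = var.format(dosage_field)
        if ds is None:
            raise ParseError(
                f"{path}: variant {var.ID or var.POS} lacks FORMAT field {dosage_field!r}"
            )
        arr = np.asarray(ds, dtype=float).reshape(-1)
        arr[arr < -0.5] = np.nan  # cyvcf2 missing sentinel
        info = np.nan
        for key in ("INFO", "R2", "DR2"):
            v = var.INFO.get(key)
            if v is not None:
                info = float(v)
                break
        records.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
                "info_score": info,
            }
        )
        cols.append(arr)
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return DosagePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# phenotypes and trait groups
# ---------------------------------------------------------------------------

def read_trait_groups(path) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'group<TAB>trait1,trait2,...'"
                )
            name, members = parts
            if name in groups:
                raise ParseError(f"{path}:{lineno}: duplicate group name {name!r}")
            groups[name] = [t.strip() for t in members.split(",") if t.strip()]
    return groups


def write_trait_groups(groups: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in groups.items():
            if name == "all":
                continue
            fh.write(f"{name}\t{','.join(members)}\n")


def read_phenotypes(
    path,
    covariate_names: Sequence[str] = (),
    group_path=None,
    sample_id_col: str | None = None,
) -> PhenotypePanel:
    """Load a phenotype TSV; non-covariate, non-id numeric columns are traits."""
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_STRINGS), dtype={0: str})
    if sample_id_col is None:
        sample_id_col = df.columns[0]
    if sample_id_col not in df.columns:
        raise ParseError(f"{path}: sample-id column {sample_id_col!r} not found")
    covariate_names = list(covariate_names)
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: covariate columns not found: {missing}")
    sample_ids = df[sample_id_col].astype(str).tolist()
    covariates = df[covariate_names].copy() if covariate_names else None
    trait_cols = [
        c
        for c in df.columns
        if c != sample_id_col
        and c not in covariate_names
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    traits = df[trait_cols].astype(float)
    groups = read_trait_groups(group_path) if group_path is not None else {}
    return PhenotypePanel(
        sample_ids=sample_ids, traits=traits, covariates=covariates, trait_groups=groups
    )


def write_phenotypes(panel: PhenotypePanel, path, sample_id_col: str = "id") -> None:
    df = pd.DataFrame({sample_id_col: panel.sample_ids})
    if panel.covariates is not None:
        df = pd.concat([df, panel.covariates.reset_index(drop=True)], axis=1)
    df = pd.concat([df, panel.traits.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def read_kinship(path, format: str = "square-tsv") -> KinshipMatrix:
    if format == "square-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ParseError(f"{path}: kinship matrix is not square: {df.shape}")
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ParseError(f"{path}: row and column sample ids differ")
        return KinshipMatrix(values=df.to_numpy(float), sample_ids=list(df.index.astype(str)))
    if format == "gcta-text":
        return _read_grm_gcta(path)
    raise ValueError(f"unknown kinship format {format!r}")


def write_kinship(K: KinshipMatrix, path, format: str = "square-tsv") -> None:
    if format == "square-tsv":
        df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    if format == "gcta-text":
        _write_grm_gcta(K, path)
        return
    raise ValueError(f"unknown kinship format {format!r}")


def _read_grm_gcta(prefix) -> KinshipMatrix:
    prefix = str(prefix)
    id_path, grm_path = prefix + ".grm.id", prefix + ".grm"
    ids = []
    with open(id_path) as fh:
        for line in fh:
            if line.strip():
                ids.append(line.split()[-1])
    n = len(ids)
    K = np.zeros((n, n))
    n_variants = None
    with open(grm_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{grm_path}:{lineno}: expected 'i j nsnps value'")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            if not (0 <= j <= i < n):
                raise ParseError(f"{grm_path}:{lineno}: index pair ({i+1},{j+1}) out of range")
            n_variants = int(float(parts[2]))
            K[i, j] = K[j, i] = float(parts[3])
    return KinshipMatrix(values=K, sample_ids=ids, n_variants=n_variants)


def _write_grm_gcta(K: KinshipMatrix, prefix) -> None:
    prefix = str(prefix)
    with open(prefix + ".grm.id", "w") as fh:
        for s in K.sample_ids:
            fh.write(f"{s}\t{s}\n")
    nv = K.n_variants if K.n_variants is not None else 0
    with open(prefix + ".grm", "w") as fh:
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{i+1}\t{j+1}\t{nv}\t{K.values[i, j]:.17g}\n")


# ---------------------------------------------------------------------------
# scan output
# ---------------------------------------------------------------------------

def write_scan(scan: ScanOutput, path) -> None:
    with open(path, "w") as fh:
        for key, val in scan.metadata.items():
            fh.write(f"#{key}={val}\n")
        scan.table.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_scan(path) -> ScanOutput:
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            try:
                metadata[key] = int(val)
            except ValueError:
                try:
                    metadata[key] = float(val)
                except ValueError:
                    metadata[key] = val
            pos = fh.tell()
        table = pd.read_csv(fh, sep="\t", na_values=list(_NA_STRINGS))
    return ScanOutput(table=table, metadata=metadata)
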