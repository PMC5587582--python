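"""End-to-end orchestration: preprocess -> mixed model -> scans -> replication.

The scan suite runs one MANOVA genome scan per trait group (the full
set plus any named subgroups), Bonferroni-corrects the genome-wide
threshold by the number of scans actually run, and collects a hit
table. Replication takes each hit through the score procedure against
one or more independent cohorts and reports Table-style columns
(P_MANOVA, beta_S, se, P_S, r_rho, P_rho) per cohort plus an
inverse-variance meta-analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinship as kinship_mod
from . import manova, preprocess, replication
from .mixed_model import TransformedPhenotypes, components_frame, transform_panel
from .types import (
    DosagePanel,
    KinshipMatrix,
    PhenotypePanel,
    ScanOutput,
    ValidationError,
    align_samples,
)


@dataclasses.dataclass
class ScanSuiteResult:
    scans: dict[str, ScanOutput]
    summaries: dict[str, dict]
    hits: pd.DataFrame
    thresholds: tuple[float, float]
    traits: pd.DataFrame  # analysis-ready (transformed) traits, sample-aligned
    panel: DosagePanel  # QC-filtered, sample-aligned dosages
    kinship: KinshipMatrix | None
    qc_report: dict
    components: pd.DataFrame | None


def prepare_cohort(
    dosages: DosagePanel,
    phenotypes: PhenotypePanel,
    covariate_names=None,
    kinship: KinshipMatrix | None = None,
    maf_min: float = 0.05,
    info_min: float = 0.30,
    use_mixed_model: bool = True,
    min_overlap: float = 0.9,
):
    """Shared front end: align, adjust+transform traits, QC variants, GRAMMAR+.

    Returns (analysis traits, filtered panel, kinship used, qc report,
    per-trait variance components or None).
    """
    if kinship is not None:
        dosages, phenotypes, kinship = align_samples(
            dosages, phenotypes, kinship, min_overlap=min_overlap
        )
    else:
        dosages, phenotypes = align_samples(dosages, phenotypes, min_overlap=min_overlap)
    adjusted = preprocess.prepare(phenotypes, covariate_names)
    panel, qc = preprocess.filter_variants(dosages, maf_min=maf_min, info_min=info_min)
    comps = None
    if use_mixed_model:
        if kinship is None:
            kinship, _ = kinship_mod.make_psd(kinship_mod.compute_grm(panel))
        else:
            kinship, _ = kinship_mod.make_psd(kinship)
        transformed: TransformedPhenotypes = transform_panel(adjusted.values, kinship)
        traits = transformed.values
        comps = components_frame(transformed.components)
    else:
        traits = adjusted.values
    return traits, panel, kinship, qc, comps, phenotypes.trait_groups


def run_scan_suite(
    dosages: DosagePanel,
    phenotypes: PhenotypePanel,
    covariate_names=None,
    kinship: KinshipMatrix | None = None,
    groups: dict[str, list[str]] | None = None,
    maf_min: float = 0.05,
    info_min: float = 0.30,
    alpha_gw: float = 5e-8,
    use_mixed_model: bool = True,
    min_overlap: float = 0.9,
) -> ScanSuiteResult:
    """One MANOVA scan per trait group; hits thresholded at alpha_gw / n_scans."""
    traits, panel, K, qc, comps, panel_groups = prepare_cohort(
        dosages,
        phenotypes,
        covariate_names=covariate_names,
        kinship=kinship,
        maf_min=maf_min,
        info_min=info_min,
        use_mixed_model=use_mixed_model,
        min_overlap=min_overlap,
    )
    if groups is None:
        groups = panel_groups
    if "all" not in groups:
        groups = {"all": list(traits.columns), **groups}
    n_scans = len(groups)
    threshold = alpha_gw / n_scans

    scans: dict[str, ScanOutput] = {}
    summaries: dict[str, dict] = {}
    best: dict[str, tuple] = {}
    for name, members in groups.items():
        out, summary = manova.scan(traits, panel, group=members, group_name=name)
        out.metadata["discovery_threshold"] = threshold
        scans[name] = out
        summaries[name] = summary
        tab = out.table
        sig = tab[tab["p_manova"] < threshold]
        for _, row in sig.iterrows():
            vid = row["variant_id"]
            if vid not in best or row["p_manova"] < best[vid][1]:
                best[vid] = (name, row["p_manova"], row)
    hit_rows = []
    for vid, (gname, p, row) in best.items():
        hit_rows.append(
            {
                "variant_id": vid,
                "chrom": row["chrom"],
                "pos": row["pos"],
                "effect_allele": row["effect_allele"],
                "best_group": gname,
                "p_manova": p,
                "n_groups_significant": sum(
                    1
                    for s in scans.values()
                    if (
                        (s.table["variant_id"] == vid)
                        & (s.table["p_manova"] < threshold)
                    ).any()
                ),
            }
        )
    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "best_group",
            "p_manova",
            "n_groups_significant",
        ],
    ).sort_values("p_manova", ignore_index=True) if hit_rows else pd.DataFrame(
        columns=[
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "best_group",
            "p_manova",
            "n_groups_significant",
        ]
    )
    thresholds = (threshold, 0.05 / max(len(hits), 1) / n_scans)
    return ScanSuiteResult(
        scans=scans,
        summaries=summaries,
        hits=hits,
        thresholds=thresholds,
        traits=traits,
        panel=panel,
        kinship=K,
        qc_report=qc,
        components=comps,
    )


def run_replication(
    hits: pd.DataFrame,
    discovery_traits: pd.DataFrame,
    discovery_panel: DosagePanel,
    groups: dict[str, list[str]],
    cohorts: dict[str, tuple[pd.DataFrame, DosagePanel]],
    n_scans: int | None = None,
    n_loci: int | None = None,
) -> pd.DataFrame:
    """Score-replicate every hit in every replication cohort.

    ``cohorts`` maps a cohort name to (analysis-ready traits, dosage
    panel) prepared via :func:`prepare_cohort`. A hit variant missing from
    a replication panel yields a flagged row, never a silent drop.
    """
    if len(cohorts) < 1:
        raise ValidationError("at least one replication cohort is required")
    n_scans = n_scans if n_scans is not None else max(len(groups), 1)
    n_loci = n_loci if n_loci is not None else max(len(hits), 1)
    _, rep_threshold = manova.significance_thresholds(
        n_scans=n_scans, n_loci=n_loci
    )
    report_columns = [
        "variant_id", "group", "cohort", "missing_in_cohort", "p_manova_rep",
        "beta_s", "se_s", "p_s", "r_rho", "p_rho", "n", "replicated",
    ]
    rows = []
    for _, hit in hits.iterrows():
        vid, gname = hit["variant_id"], hit["best_group"]
        members = groups[gname] if gname in groups else list(discovery_traits.columns)
        j = discovery_panel.variant_index(vid)
        g_disc = discovery_panel.dosages[:, j]
        ea = discovery_panel.variants["effect_allele"].iloc[j]
        Y_disc = discovery_traits[members]
        model = replication.estimate_score(
            Y_disc, g_disc, variant_id=vid, effect_allele=ea
        )
        prof_disc = replication.partial_profile(Y_disc, g_disc, variant_id=vid)
        per_cohort = []
        for cname, (traits_rep, panel_rep) in cohorts.items():
            base = {"variant_id": vid, "group": gname, "cohort": cname}
            try:
                jr = panel_rep.variant_index(vid)
            except KeyError:
                rows.append({**base, "missing_in_cohort": True})
                continue
            g_rep = panel_rep.dosages[:, jr]
            ea_rep = panel_rep.variants["effect_allele"].iloc[jr]
            rec = replication.score_and_test(
                model, traits_rep, g_rep, effect_allele_rep=ea_rep, cohort=cname
            )
            g_oriented = g_rep if ea_rep == model.effect_allele else 2.0 - g_rep
            res_manova = manova.pillai_manova(
                traits_rep[members].to_numpy(), g_oriented, variant_id=vid
            )
            prof_rep = replication.partial_profile(
                traits_rep[members], g_oriented, variant_id=vid
            )
            r_rho, p_rho = replication.profile_consistency(prof_disc, prof_rep)
            per_cohort.append(rec)
            rows.append(
                {
                    **base,
                    "missing_in_cohort": False,
                    "p_manova_rep": res_manova.p,
                    "beta_s": rec.beta_s,
                    "se_s": rec.se_s,
                    "p_s": rec.p_s,
                    "r_rho": r_rho,
                    "p_rho": p_rho,
                    "n": rec.n,
                    "replicated": bool(rec.p_s < rep_threshold and rec.beta_s > 0),
                }
            )
        if len(per_cohort) >= 2:
            beta_m, se_m, p_m = replication.meta_analyze(per_cohort)
            rows.append(
                {
                    "variant_id": vid,
                    "group": gname,
                    "cohort": "meta",
                    "missing_in_cohort": False,
                    "beta_s": beta_m,
                    "se_s": se_m,
                    "p_s": p_m,
                    "replicated": bool(p_m < rep_threshold and beta_m > 0),
                }
            )
    report = pd.DataFrame(rows, columns=report_columns if not rows else None)
    report.attrs["replication_threshold"] = rep_threshold
    return report


def export_plots_data(
    scans: dict[str, ScanOutput], alpha_gw: float = 5e-8
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Manhattan and QQ tables for each scan (plotting left to the caller)."""
    n_scans = max(len(scans), 1)
    man_frames, qq_frames = [], []
    for name, scan_out in scans.items():
        tab = scan_out.table.copy()

        def _chrom_key(c):
            try:
                return (0, int(c))
            except (TypeError, ValueError):
                return (1, str(c))

        chroms = sorted(tab["chrom"].unique(), key=_chrom_key)
        offset, offsets = 0, {}
        for c in chroms:
            offsets[c] = offset
            offset += int(tab.loc[tab["chrom"] == c, "pos"].max()) + 1
        tab["cum_pos"] = tab.apply(lambda r: offsets[r["chrom"]] + r["pos"], axis=1)
        tab["neg_log10_p"] = -np.log10(tab["p_manova"])
        tab["trait_group"] = name
        man_frames.append(
            tab[["trait_group", "variant_id", "chrom", "pos", "cum_pos", "neg_log10_p"]]
        )
        p = np.sort(tab["p_manova"].dropna().to_numpy())
        mm = len(p)
        qq_frames.append(
            pd.DataFrame(
                {
                    "trait_group": name,
                    "expected": -np.log10((np.arange(1, mm + 1) - 0.5) / mm),
                    "observed": -np.log10(p)[::-1][::-1],
                }
            )
        )
    meta = {
        "suggestive_threshold": alpha_gw,
        "significant_threshold": alpha_gw / n_scans,
    }
    return (
        pd.concat(man_frames, ignore_index=True),
        pd.concat(qq_frames, ignore_index=True),
        meta,
    )


def build_manifest(files: dict[str, str | Path], extra: dict | None = None) -> dict:
    """Run manifest: digests of every output file plus run parameters."""
    from . import __version__

    digests = {}
    for name, path in files.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        digests[name] = {"path": str(path), "sha256": h.hexdigest()}
    return {"version": __version__, "files": digests, **(extra or {})}


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
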