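"""Synthetic cohort generator.

Emulates the statistical structure of a family-based glycomics GWAS
cohort: m biallelic variants in Hardy-Weinberg equilibrium at specified
allele frequencies, family blocks produced by explicit gene-dropping
from founder haplotypes (so kinship is realistic and discrete), and k
correlated quantitative traits composed of sparse pleiotropic variant
effects, a polygenic component driven by the pedigree kinship, and
correlated environmental noise:

    Y = G_causal B' + A + E,
    A ~ MN(0, K_true, diag(h2)),    rows of E ~ N(0, (1-h2)^(1/2) Sigma_E (1-h2)^(1/2))

Every draw is reproducible bit-for-bit from (config, seed); seed streams
are split hierarchically so sub-experiments stay independently
reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DosagePanel, KinshipMatrix, PhenotypePanel, ValidationError
from . import manova
from .comparators import tates_combine


@dataclasses.dataclass
class FamilyBlock:
    """``count`` families of ``size`` sampled members each.

    kind 'sib': full siblings (both parents unsampled founders);
    kind 'parent-offspring': one sampled parent plus size-1 children of
    that parent and an unsampled founder mate.
    """

    kind: str
    size: int
    count: int

    def __post_init__(self) -> None:
        if self.kind not in ("sib", "parent-offspring"):
            raise ValidationError(f"unknown family kind {self.kind!r}")
        if self.size < 2 or self.count < 1:
            raise ValidationError("family blocks need size >= 2 and count >= 1")


@dataclasses.dataclass
class CausalVariant:
    index: int
    beta: np.ndarray  # per-trait effect (trait SD units per effect allele)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("causal effects must be finite")


@dataclasses.dataclass
class SimulationConfig:
    n: int = 1000
    m: int = 2000
    k: int = 5
    maf: float | tuple[float, float] = (0.05, 0.5)
    families: list[FamilyBlock] = dataclasses.field(default_factory=list)
    h2: float | Sequence[float] = 0.0
    sigma_e_rho: float = 0.0
    sigma_e: np.ndarray | None = None  # full k x k residual correlation, overrides rho
    causal: list[CausalVariant] = dataclasses.field(default_factory=list)
    covariates: bool = False
    dosage_jitter: float = 0.0  # sd of clipped noise mimicking imputation uncertainty
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.maf, (tuple, list)):
            lo, hi = self.maf
            if not (0 < lo <= hi < 1):
                raise ValidationError(f"invalid MAF range {self.maf}")
        elif not (0 < self.maf < 1):
            raise ValidationError(f"invalid MAF {self.maf}")
        if sum(b.size * b.count for b in self.families) > self.n:
            raise ValidationError("family block sizes sum to more than n")
        h2 = self.h2_vector()
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValidationError("h2 must lie in [0, 1]")
        S = self.sigma_e_matrix()
        if np.any(np.linalg.eigvalsh(S) <= 1e-12):
            raise ValidationError("residual trait correlation must be positive definite")
        for c in self.causal:
            if not (0 <= c.index < self.m):
                raise ValidationError(f"causal index {c.index} outside [0, {self.m})")
            if len(c.beta) != self.k:
                raise ValidationError("causal effect vector length must equal k")

    def h2_vector(self) -> np.ndarray:
        h2 = np.asarray(self.h2, dtype=float)
        return np.full(self.k, float(h2)) if h2.ndim == 0 else h2

    def sigma_e_matrix(self) -> np.ndarray:
        if self.sigma_e is not None:
            return np.asarray(self.sigma_e, dtype=float)
        S = np.full((self.k, self.k), self.sigma_e_rho)
        np.fill_diagonal(S, 1.0)
        return S

    @classmethod
    def from_dict(cls, obj: dict) -> "SimulationConfig":
        obj = dict(obj)
        obj["families"] = [FamilyBlock(**b) for b in obj.get("families", [])]
        obj["causal"] = [CausalVariant(**c) for c in obj.get("causal", [])]
        if "maf" in obj and isinstance(obj["maf"], list):
            obj["maf"] = tuple(obj["maf"])
        if obj.get("sigma_e") is not None:
            obj["sigma_e"] = np.asarray(obj["sigma_e"], dtype=float)
        return cls(**obj)


@dataclasses.dataclass
class SyntheticCohort:
    genotypes: DosagePanel
    phenotypes: PhenotypePanel
    kinship: KinshipMatrix  # true pedigree-expected relationships
    pedigree: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.maf, (tuple, list)):
        lo, hi = config.maf
        return rng.uniform(lo, hi, size=config.m)
    return np.full(config.m, float(config.maf))


def _founder_haplotypes(mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((2, len(mafs))) < mafs).astype(np.int8)


def _child_genotype(fh, mh, rng, m) -> np.ndarray:
    idx = np.arange(m)
    return fh[rng.integers(0, 2, m), idx] + mh[rng.integers(0, 2, m), idx]


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    mafs: np.ndarray | None = None,
    cohort_tag: str = "",
) -> tuple[DosagePanel, pd.DataFrame, np.ndarray]:
    """HWE founders + Mendelian gene-dropping within family blocks.

    Returns the dosage panel (hard counts, optionally jittered), a
    pedigree table, and the pedigree-expected additive relationship
    matrix (sibs and parent-offspring pairs at 0.5, diagonal 1).
    """
    m, n = config.m, config.n
    if mafs is None:
        mafs = _draw_mafs(config, rng)
    G = np.zeros((n, m), dtype=np.int8)
    kin = np.eye(n)
    ped_rows = []
    i = 0
    fam = 0
    for block in config.families:
        for _ in range(block.count):
            fam += 1
            members = list(range(i, i + block.size))
            if block.kind == "sib":
                fh, mh = _founder_haplotypes(mafs, rng), _founder_haplotypes(mafs, rng)
                for j in members:
                    G[j] = _child_genotype(fh, mh, rng, m)
                    ped_rows.append((f"{cohort_tag}s{j+1}", f"fam{fam}", "sib"))
            else:  # parent-offspring
                ph = _founder_haplotypes(mafs, rng)
                mate = _founder_haplotypes(mafs, rng)
                G[members[0]] = ph.sum(axis=0)
                ped_rows.append((f"{cohort_tag}s{members[0]+1}", f"fam{fam}", "parent"))
                for j in members[1:]:
                    G[j] = _child_genotype(ph, mate, rng, m)
                    ped_rows.append((f"{cohort_tag}s{j+1}", f"fam{fam}", "offspring"))
            # expected additive relationship: 0.5 for all sampled pairs in
            # these block kinds (sib-sib, parent-child)
            for a_i, a in enumerate(members):
                for b in members[a_i + 1:]:
                    kin[a, b] = kin[b, a] = 0.5
            i += block.size
    if i < n:
        G[i:] = rng.binomial(2, mafs, size=(n - i, m)).astype(np.int8)
        for j in range(i, n):
            ped_rows.append((f"{cohort_tag}s{j+1}", f"u{j+1}", "unrelated"))

    dosages = G.astype(float)
    info = np.full(m, np.nan)
    if config.dosage_jitter > 0:
        noise = rng.normal(0.0, config.dosage_jitter, size=dosages.shape)
        dosages = np.clip(dosages + noise, 0.0, 2.0)
        var_g = 2 * mafs * (1 - mafs)
        info = var_g / (var_g + config.dosage_jitter**2)

    chrom = 1 + (np.arange(m) * 22) // m
    pos = np.zeros(m, dtype=int)
    for c in range(1, 23):
        sel = chrom == c
        pos[sel] = 10_000 * (1 + np.arange(sel.sum()))
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j+1}" for j in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "info_score": info,
        }
    )
    pedigree = pd.DataFrame(ped_rows, columns=["sample_id", "family_id", "role"])
    panel = DosagePanel(
        sample_ids=pedigree["sample_id"].tolist(), variants=variants, dosages=dosages
    )
    return panel, pedigree, kin


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: DosagePanel,
    kinship_true: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PhenotypePanel, dict]:
    """Traits = causal variant effects + polygenic background + correlated noise."""
    n, k = panel.n, config.k
    h2 = config.h2_vector()
    S = config.sigma_e_matrix()
    L_k = np.linalg.cholesky(kinship_true + 1e-10 * np.eye(n))
    A = (L_k @ rng.standard_normal((n, k))) * np.sqrt(h2)
    C = np.linalg.cholesky(S)
    E = (rng.standard_normal((n, k)) @ C.T) * np.sqrt(1.0 - h2)
    Y = A + E
    for cv in config.causal:
        g = panel.dosages[:, cv.index]
        Y = Y + np.outer(g - g.mean(), cv.beta)

    covariates = None
    cov_truth = {}
    if config.covariates:
        age = rng.uniform(20.0, 80.0, n)
        sex = rng.integers(0, 2, n)
        b_age, b_sex = 0.02, 0.5
        Y = Y + b_age * (age - age.mean())[:, None] + b_sex * (sex - 0.5)[:, None]
        covariates = pd.DataFrame({"age": age, "sex": sex.astype(int)})
        cov_truth = {"beta_age": b_age, "beta_sex": b_sex}

    trait_names = [f"GP{j+1}" for j in range(k)]
    traits = pd.DataFrame(Y, columns=trait_names)
    phen = PhenotypePanel(
        sample_ids=list(panel.sample_ids),
        traits=traits,
        covariates=covariates,
        trait_groups=default_trait_groups(trait_names),
    )
    truth = {
        "h2": h2,
        "sigma_e": S,
        "polygenic": A,
        "causal": config.causal,
        **cov_truth,
    }
    return phen, truth


#: subgroup name -> fraction of traits and stride, echoing the eight
#: chemistry-based glycan subsets (galactosylation spans most traits,
#: sialylation a mid-sized subset, etc.)
_GROUP_PLAN = [
    ("galactosylation", 17 / 23, 1),
    ("monogalactosylation", 6 / 23, 2),
    ("digalactosylation", 6 / 23, 3),
    ("sialylation", 8 / 23, 1),
    ("monosialylation", 4 / 23, 2),
    ("disialylation", 4 / 23, 3),
    ("fucosylation", 10 / 23, 2),
    ("bisecting_glcnac", 6 / 23, 1),
]


def default_trait_groups(trait_names: Sequence[str]) -> dict[str, list[str]]:
    """Eight deterministic, overlapping subsets of the trait list.

    Mimics grouping traits by shared chemistry: each group takes a strided
    slice whose size is proportional to the corresponding glycan subset in
    a 23-trait panel (minimum 2 traits). For k < 3 no subgroups are made.
    """
    k = len(trait_names)
    if k < 3:
        return {}
    groups = {}
    for g_i, (name, frac, stride) in enumerate(_GROUP_PLAN):
        size = max(2, round(frac * k))
        idx = [(g_i + stride * j) % k for j in range(size)]
        seen: list[int] = []
        for ix in idx:
            if ix not in seen:
                seen.append(ix)
        while len(seen) < size:  # stride hit a cycle; fill sequentially
            for ix in range(k):
                if ix not in seen:
                    seen.append(ix)
                    break
        groups[name] = [trait_names[ix] for ix in seen]
    return groups


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig, seed: int | None = None, cohort_tag: str = ""
) -> SyntheticCohort:
    """One cohort, reproducible bit-for-bit from (config, seed)."""
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_g, rng_p = (np.random.default_rng(s) for s in ss.spawn(2))
    panel, pedigree, kin = simulate_genotypes(config, rng_g, cohort_tag=cohort_tag)
    phen, truth = simulate_phenotypes(panel, kin, config, rng_p)
    truth["mafs"] = panel.maf()
    K = KinshipMatrix(
        values=kin, sample_ids=list(panel.sample_ids), estimator="pedigree-expected"
    )
    return SyntheticCohort(
        genotypes=panel, phenotypes=phen, kinship=K, pedigree=pedigree, truth=truth
    )


def simulate_cohorts(
    config: SimulationConfig, ns: Sequence[int], seed: int | None = None
) -> list[SyntheticCohort]:
    """Discovery + replication cohorts sharing MAFs and causal ground truth.

    ``ns`` gives each cohort's sample size (family structure scales with
    the same blocks as long as they fit; blocks that no longer fit are
    dropped proportionally).
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    maf_rng = np.random.default_rng(ss.spawn(1)[0])
    mafs = _draw_mafs(config, maf_rng)
    cohorts = []
    child_seeds = ss.spawn(len(ns) + 1)[1:]
    for c_i, (n_c, child) in enumerate(zip(ns, child_seeds)):
        cfg = dataclasses.replace(config, n=n_c, families=_fit_families(config.families, n_c))
        rng_g, rng_p = (np.random.default_rng(s) for s in child.spawn(2))
        tag = f"c{c_i+1}_"
        panel, pedigree, kin = simulate_genotypes(cfg, rng_g, mafs=mafs, cohort_tag=tag)
        phen, truth = simulate_phenotypes(panel, kin, cfg, rng_p)
        truth["mafs"] = mafs
        K = KinshipMatrix(
            values=kin, sample_ids=list(panel.sample_ids), estimator="pedigree-expected"
        )
        cohorts.append(
            SyntheticCohort(
                genotypes=panel, phenotypes=phen, kinship=K, pedigree=pedigree, truth=truth
            )
        )
    return cohorts


def _fit_families(families: list[FamilyBlock], n: int) -> list[FamilyBlock]:
    out, used = [], 0
    for b in families:
        count = min(b.count, max(0, (n - used) // b.size))
        if count:
            out.append(FamilyBlock(b.kind, b.size, count))
            used += count * b.size
    return out


# ---------------------------------------------------------------------------
# power comparison
# ---------------------------------------------------------------------------

_PATTERNS = {
    # alternating signs: the joint signal is strong while each marginal
    # effect stays modest — the regime where multivariate tests win
    "diffuse": lambda k: np.array([(-1.0) ** j for j in range(k)]) / np.sqrt(k),
    "single": lambda k: np.eye(k)[0],
}


def power_experiment(
    effect_sizes: Sequence[float],
    scenario: str = "diffuse",
    n: int = 1000,
    k: int = 5,
    rho: float = 0.5,
    maf: float = 0.3,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical power of MANOVA vs univariate-Bonferroni vs TATES-style.

    One causal variant per replicate with effect ``effect * pattern`` on k
    exchangeably correlated traits; rejection frequencies at ``alpha``
    with binomial standard errors.
    """
    if scenario not in _PATTERNS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    if n_reps < 50:
        import warnings

        warnings.warn("n_reps < 50 gives wide power intervals")
    pattern = _PATTERNS[scenario](k)
    Sigma = np.full((k, k), rho)
    np.fill_diagonal(Sigma, 1.0)
    C = np.linalg.cholesky(Sigma)
    rng = np.random.default_rng(seed)
    rows = []
    for effect in effect_sizes:
        beta = effect * pattern
        hits = {"manova": 0, "univariate-bonferroni": 0, "tates": 0}
        for _ in range(n_reps):
            g = rng.binomial(2, maf, n).astype(float)
            Y = np.outer(g - g.mean(), beta) + rng.standard_normal((n, k)) @ C.T
            res = manova.pillai_manova(Y, g)
            if res.p < alpha:
                hits["manova"] += 1
            p_uni = _univariate_p(Y, g)
            if p_uni.min() * k < alpha:
                hits["univariate-bonferroni"] += 1
            R = np.corrcoef(Y, rowvar=False)
            if tates_combine(p_uni, R) < alpha:
                hits["tates"] += 1
        for method, h in hits.items():
            pw = h / n_reps
            rows.append(
                {
                    "scenario": scenario,
                    "effect": effect,
                    "method": method,
                    "power": pw,
                    "se": np.sqrt(pw * (1 - pw) / n_reps),
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def _univariate_p(Y: np.ndarray, g: np.ndarray) -> np.ndarray:
    n, k = Y.shape
    gc = g - g.mean()
    Yc = Y - Y.mean(axis=0)
    ss_g = float(gc @ gc)
    r = (gc @ Yc) / np.sqrt(ss_g * np.einsum("ij,ij->j", Yc, Yc))
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), 5e-324, 1.0)
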