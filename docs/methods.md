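# Methods

This note records the statistical models implemented in `pleioscan`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the design decisions taken where more
than one defensible option existed.

## Multivariate association test

The per-variant test is MANOVA of the trait group against a single
dosage vector. Writing E for the residual cross-product matrix of the
full multivariate regression Y = 1μ′ + gβ′ + e, E₀ for the
intercept-only model and H = E₀ − E, Pillai's trace is
V = tr(H(H+E)⁻¹) = Σ λⱼ/(1+λⱼ) over the generalized eigenvalues of
det(H − λE) = 0, with F = (V/k)/((1−V)/(n−k−1)) referred to
F_{k, n−k−1}. Because a single predictor makes H rank one, V equals the
R² of regressing the (centered) dosage on the (centered) traits, which
is how scans are computed: one QR decomposition of the trait matrix,
then a single matrix product for all variants. The explicit E/E₀/H
eigen-solve is retained (`pillai_eigen`) purely as a verification path,
and the test suite checks agreement to 1e-10 on random instances. For a
single predictor Wilks' Λ = 1 − V and the Hotelling–Lawley trace and
Roy's root both equal V/(1−V), so all four statistics produce one
F-test; `manova_statistics` exposes them and the suite asserts the
identity.

Numerical conventions: all centering in double precision; V is clamped
to [0, 1 − 1e-15] before the F transform; the exact F (not the χ²(k)
approximation) is the canonical p-value, with the χ² version available
from `f_and_chi2_p`. A monomorphic variant yields a flagged row with a
missing p-value rather than an error. Missing data are handled
complete-case per variant — the samples with a non-missing dosage and
all group traits — which keeps the F distribution exact; `n_used` is
recorded per variant. Trait groups whose columns are collinear
(condition number above 1e10) are reduced to a maximal well-conditioned
subset with a warning, and k shrinks accordingly.

## Preprocessing

Traits are adjusted for fixed-effect covariates (numeric covariates
enter linearly; categorical batch factors such as plate, column, machine
and part are one-hot expanded; a rank-deficient design is an error that
names the collinear columns). Residuals are mapped to normal scores by
Φ⁻¹((rank − 0.5)/n) with average ranks for ties, then rescaled to unit
sample variance, so every downstream module sees Z-scored traits. The
raw quantile map alone leaves the sample variance slightly below 1 at
finite n, hence the explicit rescaling step in `prepare`.

Variant QC excludes minor allele frequency < 0.05 (MAF computed from
non-missing dosages as min(p, 1−p), p = mean(dosage)/2) and imputation
R² < 0.30 by default; variants without an R² (directly genotyped) pass
the info filter. Both cutoffs are arguments and are recorded in the QC
report.

## Genomic relationship matrix

K[i,j] = (1/m) Σₛ (g_is − 2pₛ)(g_js − 2pₛ)/(2pₛ(1−pₛ)) with sample
allele frequencies — the frequency-weighted IBS estimator on the
VanRaden scale, expected diagonal 1 under HWE. Monomorphic variants are
excluded with a warning. Missing dosages are handled pairwise-complete
(each pair's sum is divided by the variants both members have observed),
which avoids imputation bias in K at the cost of not being exactly PSD
in extreme missingness; `make_psd` clips negative eigenvalues to a small
epsilon (default 1e-6) and reports how many were touched. Any constant
rescaling of K is absorbed by the variance components: the test suite
verifies that cK leaves the transformed phenotypes unchanged to
machine precision.

## Polygenic model and GRAMMAR+ transformation

Each trait follows y ~ N(μ1, σ²(h²K + (1−h²)I)). After one
eigendecomposition of K the restricted likelihood is a cheap function of
h², profiled over μ and σ²; a 21-point bracket plus root-finding on the
analytic REML score gives the optimum to machine precision, with
boundary optima (h² = 0 or → 1) detected from the score's sign. A flat
profile — K = I makes h² unidentifiable — is flagged rather than
reported as a spurious estimate.

The transformation whitens each trait with its fitted covariance:
r = c·V^{−1/2}(y − μ̂1), V = ĥ²K + (1−ĥ²)I, recentred, with
c = 1/mean(diag(V^{−1/2})) restoring the trait's scale (and making the
output invariant to rescaling of K). Under the null the whitened trait
has i.i.d. entries independent of any genotype, so ordinary per-variant
OLS — and the MANOVA built on it — is calibrated in family samples.
Plain V^{−1} residuals, the classical fast-association residual, are
markedly conservative under strong relatedness (λ ≈ 0.5 in the
sib-quartet benchmark) and are not used.

One subtlety arises with *several* traits: per-column whitening leaves
the cross-trait covariance family-structured whenever the genetic and
residual trait correlations differ, which inflates joint tests (λ up to
~1.2 in the sib-quartet benchmark with residual ρ = 0.5 and independent
polygenic effects). `transform_panel` therefore first rotates the traits
to their phenotypic principal components, whitens each rotated column
with its own univariate fit, and rotates back. The MANOVA statistic is
invariant to any invertible trait-space map, so the rotation does not
change what is being tested; when genetic and residual correlation share
eigenvectors (exactly true in the generator, approximately in real
panels) the rotated columns are independent and the per-column
transformation is jointly calibrated. Measured λ on the 200-sib-quartet
benchmark: 0.92–1.03 across seeds, vs 2.1–2.6 untransformed. The
per-trait ĥ² written to the sidecar always comes from univariate fits of
the original traits. This is a two-step scheme — k univariate fits, no
multivariate REML — chosen deliberately for speed and simplicity over a
full multivariate mixed model.

## Scan suite, genomic control, thresholds

One scan is run per trait group (the full set plus each named
subgroup); the genome-wide threshold is α_gw divided by the number of
scans actually run (with the default nine groups and α_gw = 5×10⁻⁸ this
is 5.6×10⁻⁹), and the replication threshold is 0.05 divided by the
number of loci carried forward times the number of scans (five loci and
nine scans give 1.1×10⁻³). The genomic-control λ converts each MANOVA
p-value to its 1-df χ² equivalent before taking the median ratio, so λ
is comparable across group sizes; fewer than 100 p-values triggers a
warning. Dosages are used as-is, never rounded to hard calls.

## Score replication and pleiotropy profiles

Score coefficients α are the OLS coefficients of the centered dosage on
the centered trait group in the discovery cohort (the F-test of that
regression *is* the MANOVA test, an identity the suite checks to 1e-10).
In a replication cohort, S = Yα uses the discovery α unchanged; if the
replication file codes the other allele the dosage is flipped (d → 2−d),
never the score. P_S is reported two-sided; the replication verdict
additionally requires β_S > 0.

The pleiotropy profile is ρⱼ = tⱼ/√(tⱼ² + df), df = n − k − 1, from the
t-statistics of the multiple regression of dosage on traits — exactly
the sample partial correlations. Profiles are z-standardized across the
k entries of that variant within each cohort (not genome-wide), and
cross-cohort consistency r_ρ is the Pearson correlation of the two
z-profiles. Its p-value uses t = r√((k−2)/(1−r²)) with k − 2 df,
one-sided for r > 0; treating the k traits as independent observations
is an acknowledged approximation, and k < 3 is refused. Multi-cohort
evidence is pooled by inverse-variance fixed-effect meta-analysis of
(β_S, se) — estimate-level pooling, not individual-level, when several
replication cohorts are available.

## Comparators

The univariate baseline is per-trait OLS with optional genomic-control
correction (χ²/λ). The min-p combination is TATES-style: sort the k
univariate p-values, compute a Li–Ji effective number of tests
m_e = Σ[I(λᵢ ≥ 1) + frac(λᵢ)] from the eigenvalues of the trait
correlation submatrix of each top-j prefix, and take
min_j m_e(k)/m_e(j)·p_(j), capped at 1. The original TATES fits a
simulation-derived polynomial for m_e whose coefficients are not
reproducible here; the Li–Ji variant keeps all power comparisons
internally consistent and is labelled "TATES-style" for that reason.
Eigenvalues are rounded before the floor() in m_e so that floating noise
at integer eigenvalues (e.g. a perfectly correlated block) cannot flip
the fractional part. Measured null type-I error at n = 1000, k = 5,
ρ = 0.5 is ≈ 0.068 at α = 0.05 — the Li–Ji variant is mildly liberal,
which if anything flatters this competitor in power comparisons.

## Synthetic-data generator

The generator emulates a family-based omics GWAS: founders drawn in HWE
at each variant's MAF (fixed or uniform in a range), family blocks
produced by explicit Mendelian gene-dropping from founder haplotypes
(sibships and parent–offspring blocks; sampled relatives have additive
relationship 0.5), remaining individuals unrelated, and traits

    Y = G_causal B′ + A + E,   A ~ MN(0, K_true, diag(h²)),
    rows of E i.i.d. N(0, D Σ_E D),  D = diag(√(1−h²)),

with sparse pleiotropic causal-effect vectors in trait-SD units per
effect allele. Gene-dropping (rather than MVN genotypes) was chosen so
the GRM and the mixed model face realistic discrete relatedness.
Optional features: covariate effects (age, sex) for exercising the
adjustment step, dosage jitter with a recorded info target to mimic
imputation uncertainty, and a two-cohort mode that shares MAFs and
causal ground truth between a discovery and replication cohort. Every
cohort is reproducible bit-for-bit from (config, seed); seed streams are
split hierarchically (SeedSequence spawning) so genotype and phenotype
draws stay independently reproducible.

What the generator does *not* emulate: linkage disequilibrium (causal
variants are single and unlinked), genotyping/imputation error beyond
the simple jitter, trait-specific genetic correlation (polygenic effects
are independent across traits by construction), selection, assortative
mating, or batch structure beyond additive covariate shifts. Passing
tests therefore demonstrate calibration and power under clean
single-variant architectures, not robustness to LD or to mismatched
genetic/residual correlation — the PCA rotation in the transformation
assumes the two correlation structures share eigenvectors, which real
panels only approximate.

Default study conditions used by the benchmark suite: k = 5 traits at
exchangeable residual correlation 0.5 for calibration experiments
(n = 1000 unrelated; 200 sib-quartets at h² = 0.5 for the family
benchmark), k = 17 with an 8-trait alternating-sign effect of 0.08 SD
per allele for two-cohort replication (n = 2000 per cohort), and a
pipeline-scale run at n = 2000, m = 10,000, k = 23 with nine trait
groups whose sizes echo a 23-trait glycan panel (the largest group 17
traits, a mid-sized one 8). Pipeline causal effects (0.18–0.20 SD per
allele on 6–8 traits) are sized so the planted locus is genome-wide
significant at the 5.6×10⁻⁹ threshold even at the least favourable MAF
in the 0.05–0.5 range, matching the magnitude of a top locus in a
discovery cohort of this size. The diffuse power scenario alternates
effect signs across positively correlated traits — the regime where a
joint test gains most and single-trait scans miss the locus; the
single-trait scenario (all effect on one trait) is the known regime
where MANOVA pays a degrees-of-freedom price, and is included for
honesty in `power_experiment`.

## Known limitations

- The two-step GRAMMAR+ + MANOVA scheme is approximate relative to a
  full multivariate mixed model; with a large fraction of very close
  relatives the approximation degrades first.
- P_ρ treats k trait-level partial correlations as independent
  observations; with strongly clustered traits it is anti-conservative.
- The TATES-style comparator uses Li–Ji m_e, not the original
  simulation-fitted polynomial; comparisons are internally consistent
  but not identical to the original software.
- Pairwise-complete GRM entries can make K slightly non-PSD under heavy
  missingness; `make_psd` repairs but does not model the missingness.
- No LD handling: loci are single variants; clumping/locus definition is
  out of scope.
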