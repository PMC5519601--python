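# Methods

## The model

`envgreml` estimates genome-wide genotype-by-environment interaction (G×E)
for a quantitative trait measured once per individual in one of K discrete
environment groups. The model treats the same trait in different
environments as K correlated traits measured on *disjoint* individuals:

    y_i = X_i b_i + Z_i g_i + e_i,        i = 1..K

with `g ~ N(0, Sigma_g ⊗-structured A)` and `e_i ~ N(0, sigma2_e_i I)`.
`A` is the allele-frequency standardized genomic relationship matrix (GRM)

    A_jk = (1/M_jk) * sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m)),

so the phenotypic covariance matrix is block-structured:

    V[i, j] = sigma_g_ij * A[idx_i, idx_j] + delta_ij * sigma2_e_i * I.

Because no individual is observed in two environments, the residual
covariance between blocks is structurally zero in G×E mode. In multi-trait
mode (several traits on overlapping individuals) the residual covariance
sigma_e_ij is estimated on the entries where blocks share individuals —
omitting it would inflate the genetic covariance.

With several GRMs (e.g. SNPs partitioned into functional categories) one
genetic covariance matrix is fitted per GRM with a shared residual
structure; `partition_ratio` reports each category's share of genetic
(co)variance with a delta-method SE and a one-sided enrichment test
against the category's SNP fraction.

The G×E signal is the cross-environment genetic correlation

    r_G(i, j) = sigma_g_ij / sqrt(sigma2_g_i * sigma2_g_j),

tested against 1 (no interaction) with a two-sided Wald test whose SE
comes from the first-order delta method on the inverse information matrix.
r_G is deliberately *unconstrained* — sampling noise can push estimates
past 1, and such estimates must be representable rather than clipped.

## Estimation

`reml_fit` maximizes the restricted likelihood

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

by average-information (AI) REML:

- **Start values:** sigma2_g_i = sigma2_e_i = var(y_i)/2 per block (split
  evenly across GRM components); covariances start at 0.
- **Warm-up:** one generalized EM step on the variance parameters
  (covariances held for that step) — robust far from the optimum.
- **AI iterations:** Newton-like steps with the average-information matrix,
  with three safeguards: (1) an *active set* — variance parameters pinned
  at their floor with an outward gradient are frozen out of the solve;
  (2) *Levenberg–Marquardt damping* — if the undamped AI direction fails,
  ridge-damped directions (which interpolate toward the gradient, a
  guaranteed ascent direction) are tried; (3) *step halving* — a proposal
  is accepted only if it does not decrease logL, so the likelihood trail
  is monotone.
- **Constraints:** variances are floored at 1e-6 × var(y_i) (flagged as
  `boundary` when pinned); covariances are free.
- **Convergence:** |Δ logL| < 1e-6 (configurable). Non-convergence raises
  a diagnostic error carrying the likelihood trail, or flags the result
  (`on_fail="flag"`).
- **Inference:** the AI matrix at the optimum serves as the information
  matrix; its inverse gives the asymptotic covariance for delta-method SEs
  of h², r_G and partition ratios. When the information matrix is singular
  (e.g. A = I makes genetic and residual variance unidentifiable) the fit
  is flagged non-identifiable and no SE is reported.

### A numerical caveat worth knowing

When the GRM is rank-deficient (fewer SNPs than samples) and the genetic
covariance matrix is allowed to be indefinite, V can be driven toward
singularity, where log|V| inflates the restricted likelihood and swamps it
with rounding error. `_reml_state` therefore rejects any V whose
reciprocal condition number (from the Cholesky diagonal) falls below 1e-9,
and all simulation studies in this package use M ≥ 1.5 × N so the GRM is
full-rank. Real GWAS data are far inside the safe regime (hundreds of
thousands of SNPs against tens of thousands of samples); the guard matters
only for aggressive desk-scale simulation.

At small group sizes the *statistics* (not the numerics) routinely produce
boundary solutions: SE(sigma2_g) ≈ sqrt(2M)/n, so with n = 120 per group
and true h² = 0.4 the unconstrained optimum floors a variance in a
sizeable fraction of datasets. Scan results keep every pairwise contrast
in the output (K(K−1)/2 rows) with undefined estimates reported as NaN and
a warning, so the multiple-testing accounting stays structural.

## The synthetic-data generator

The generator mirrors the model's own assumptions (which is the point: it
makes parameter recovery a well-defined test of the estimator, not of the
generator):

- **Genotypes:** unlinked biallelic SNPs, p ~ U(maf_range), dosage ~
  Binomial(2, p); optional missingness completely at random. No LD, no
  realistic MAF spectrum, no imputation uncertainty.
- **Architecture:** infinitesimal — every SNP causal. Cross-group
  covariance is induced at the SNP-effect level: per-SNP effect vectors for
  the K groups are drawn as `B = Z L'` with `L L' = Sigma_g / M`, and
  genetic values are `g = W B` on the standardized dosage matrix W. Groups
  contain disjoint individuals.
- **Covariates:** linear and additive (continuous, binary, or 4-level
  factors with the first level as reference); they confound the phenotype
  until removed by `adjust_phenotype`.
- **Non-normal options:** an exponential transform (skew) and an ordinal
  discretization (4 levels) exercise the inverse-normal-transform pathway.
- **Selection:** `apply_selection` truncates on the standardized phenotype
  (or a variable correlated r with it), keeping t1 < s < t2.

What passing tests on this generator do *not* establish: robustness to LD
(the GRM estimator and GBLUP≡ridge identity are insensitive to it, but
partitioned-GRM enrichment is not), to assortative structure or
relatedness (pruned upstream in real use), or to confounders not expressible
as linear covariate effects.

## Phenotype preparation

OLS adjustment for fixed covariates on the full sample before
stratification (matching the usual pre-adjustment workflow; per-group
re-standardization would not change r_G and is available). Collinear
design columns are dropped with a warning; rows with missing covariates
are deleted listwise and reported. The inverse normal transform uses the
Blom offset, v → Φ⁻¹((rank − 3/8)/(n + 1/4)), average ranks for ties; the
offset is the common choice in genetic epidemiology and the transform is
invariant to monotone re-expression of the input. INT is applied before
stratification by default.

## Truncation-selection theory

For a standardized trait y = g + e, interval truncation t1 < s < t2 on a
selection variable s (the phenotype itself, or a variable with correlation
r to it) yields closed-form post-selection moments in terms of the
upper-tail proportions K_j = 1 − Φ(t_j) and intensities i_j = φ(t_j)/K_j.
The central identity: within each truncated group the genetic values
satisfy g_s = c + b·g, an affine rescaling, so the genetic correlation
between two independently truncated groups is *exactly* the pre-selection
r_G — ascertainment by truncation (e.g. environment groups formed by
selecting on a phenotype-correlated variable) cannot create spurious G×E.
The package verifies this both in closed form and end-to-end (simulate →
truncate → re-estimate with GREML).

Two documented subtleties:

1. **Correlated-variable case.** The published closed forms in the source
   literature set E(g_s) = 0 on the argument that the environmental
   variable has no genetic component; under the standard bivariate-normal
   construction s = r·y + sqrt(1−r²)·ε (the one a simulation naturally
   uses) the selected genetic mean is r·h²·E(s|selected) ≠ 0, while the
   published *second* moment E(g_s²) is exact under that construction. No
   simulation satisfies both published first and second moments at once.
   `correlated_selection_moments` defaults to the internally consistent
   set (mean retained; identical E(g_s²), b, and the r_G-invariance
   identity); `as_printed=True` reproduces the published convention.
2. **Direction of the heritability change.** Because
   var(g | selected) = h⁴·var(y_s) + h²(1−h²), truncation shrinks
   phenotypic variance *more* than genetic variance, so the variance-ratio
   heritability of the selected sample satisfies h²_s ≥ h² and can exceed
   1 (the selected residual covaries negatively with the genetic value).
   The closed forms, the Monte-Carlo oracle and the property tests agree
   on this direction.

Infinite thresholds are handled by the limit conventions φ(±∞) = 0,
φ(t)·t → 0.

## Permutation test

The permutation null for a contrast shuffles the environment labels of the
two groups jointly, preserving both group sizes exactly, and refits the
bivariate model per shuffle (warm-started at the observed estimates). The
statistic is |r̂_G − 1| — the deviation from the no-G×E null being tested.
The empirical p uses the add-one estimator (1 + #{null ≥ observed})/(n+1),
so p ≥ 1/(n_perm+1). Shuffles whose fit does not converge or lands on a
variance floor are redrawn once cold-started, then counted as failures;
more than 20% failures aborts the test.

## Prediction and GWAS

GBLUP predicts target genetic values from discovery phenotypes under the
single-GRM model, with the intercept absorbed by GLS:
ĝ_t = A[t, d] (A[d, d] + λI)⁻¹ (y_d − μ̂), λ = (1−h²)/h². This is
algebraically identical to ridge regression on the standardized SNP matrix
with penalty M·λ when A = ZZ'/M; the package carries both forms and tests
their agreement to 1e-8. The shrinkage h² is re-estimated in the discovery
set by REML by default (a fixed override exists). Accuracy is the Pearson
correlation between prediction and the adjusted phenotype in a target set
disjoint from discovery. Because the target is the phenotype,
accuracy is bounded by sqrt(h²)·cor(ĝ, g); at the desk-scale study sizes
(discovery 800, M = 1200, h² = 0.2) the same-environment accuracy is
around 0.15. Under G×E, cross-environment accuracy is attenuated by
roughly the factor r_G relative to same-environment accuracy, and the
simulation study measures how often the same-environment design wins —
a comparison with a modest margin at this scale.

The GWAS scan is per-SNP simple linear regression of the (pre-adjusted)
phenotype on dosage over the samples non-missing at that SNP, with
genome-wide significance annotated at 5e-8 and genomic-control
λ = median(χ²)/0.4549 for calibration checks. Monomorphic SNPs are flagged,
not tested.

## Simulation-study problem sizes

The studies in `envgreml.studies` (used by `scripts/acceptance.py` and the
acceptance tests) run at desk scale, chosen so each completes in minutes
on one CPU while keeping the statistical meaning of the check (bias
tolerances are Monte-Carlo self-scaling; calibration intervals use exact
binomial bounds at the stated replicate count):

| study | defaults |
|---|---|
| REML vs direct-likelihood oracle | n=60, M=120, h²=0.8 |
| parameter recovery (h²=0.2, r_G=0.6) | 30 reps, n=500/group, M=1500 |
| Wald type-I error (r_G=1) | 200 reps, n=300/group, M=900, h²=0.3 |
| selection moments vs MC | 7-point grid × 1e6 draws |
| r_G invariance under truncation | 20 reps, n=600/group pools, M=1400, h²=0.5 |
| permutation calibration | 20 datasets × 200 shuffles, n=150/group, M=500, h²=0.5 |
| GBLUP identity / same-vs-cross | 20 reps, discovery 800, target 250, M=1200, h²=0.2, r_G=0.5 |
| GWAS null λ | n=500, M=2000 |

Recovery studies summarize r_G with the pooled ratio-of-replicate-means
estimator (jackknife SE): the per-replicate ratio c/sqrt(v1 v2) is
heavy-tailed whenever a variance estimate lands near zero, while the
pooled ratio is a consistent, finite-variance estimator of the same
quantity. Per-group h² keeps the per-replicate mean (a bounded statistic).

Two design rules behind these numbers: M ≥ 1.5 × total N (full-rank GRM;
see the numerical caveat), and group sizes large enough that
SE(sigma2_g) ≈ sqrt(2M)/n keeps boundary solutions rare under the study's
true h². The REML-oracle instance uses h² = 0.8 so its optimum is interior
for any seed. The selection-moment check applies a pre-registered
two-stage rule: with ~35 moment comparisons at 3 MC SE, one excursion is
expected noise, so an excursion is re-tested once against an independent
4×-draw Monte-Carlo and only a persistent excursion fails.

## Known limitations

- Dense O(N³) algebra per AI iteration: intended for cohorts up to a few
  thousand; no sparse, low-rank, or out-of-core paths.
- Genotype simulation has no LD; enrichment analyses on real (LD-rich)
  data need category definitions robust to tagging, which is out of scope.
- The HWE filter is the 1-df chi-square without continuity correction (no
  mid-p exact test); adequate at the sample sizes where the filter is used.
- The permutation test refits per shuffle; at biobank scale one would
  precompute transforms per pair, which is not implemented.
- Eight-group (environment × sex) scans at small per-group n routinely pin
  variances at the floor; their contrasts are reported as undefined rather
  than invented.
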