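# envgreml

Genome-wide genotype-by-environment interaction (G×E) analysis for
quantitative traits measured in discrete environment groups, using
multivariate GREML on SNP data.

Many early-life exposures (breastfeeding, maternal smoking, …) define
groups of *different* people — nobody is observed in both environments —
so classical repeated-measures G×E designs do not apply. `envgreml`
implements the alternative: treat the trait in each environment as a
separate trait, estimate the full genetic covariance structure across
groups from a genomic relationship matrix (GRM), and test whether the
cross-environment genetic correlation

&nbsp;&nbsp;&nbsp;&nbsp; r_G(i, j) = σ_g,ij / √(σ²_g,i · σ²_g,j)

is below 1 — the genome-wide signature of G×E. The package is aimed at
quantitative geneticists and epidemiologists who want this analysis as a
tested, scriptable Python library rather than a monolithic binary.

## What's inside

- **`reml_fit`** — multivariate average-information REML: K environment
  groups (disjoint individuals, residual covariance structurally zero) or
  K traits (shared individuals, residual covariance estimated), one or
  more GRMs (functional partitioning), variance floors, active-set /
  damped AI updates with monotone likelihood, delta-method SEs from the
  information matrix.
- **`genetic_correlation`, `wald_test`, `partition_ratio`** — r_G with SE
  and tests against 0 and 1; per-category share of genetic (co)variance
  with an enrichment test against the SNP fraction.
- **`gxe_scan`, `sex_stratified_scan`, `permutation_test`,
  `bonferroni_threshold`** — the study design: one joint K-variate fit,
  all K(K−1)/2 contrasts, family-wise correction over traits × contrasts,
  label-shuffling permutation nulls that preserve group sizes.
- **`selection.*`** — closed-form truncated-selection theory: post-selection
  moments, the affine identity g_s = c + b·g, and the proof-by-construction
  that truncation ascertainment leaves r_G unbiased (no spurious G×E),
  with a Monte-Carlo cross-check.
- **`gblup_predict`, `rrblup_predict`, `gwas_scan`** — cross-environment
  genomic prediction (GRM-form GBLUP ≡ SNP ridge regression) and per-group
  single-SNP association with genomic-control λ.
- **`genotype I/O & QC`** — PLINK1 bed/bim/fam reader/writer, GCTA binary
  GRM reader/writer, MAF/HWE/missingness filters, greedy relatedness
  pruning.
- **`simulate.*`** — a synthetic-cohort generator with known truth:
  per-group heritabilities, an arbitrary K×K genetic correlation matrix,
  covariate confounding, non-normal options and truncation selection.
- **`studies.*`** — reproducible simulation studies of the statistical
  properties (bias, type-I error, calibration), used by the acceptance
  script and the test suite.

See `docs/methods.md` for the model, estimation details and design
decisions, and `examples/` for one narrative script per capability.

## Worked example

A two-environment cohort with true per-group h² = 0.5 and true
r_G = 0.3 — genuine G×E (from `examples/03_gxe_scan.py`):

```python
import envgreml as eg

n, m = 350, 1100
G = eg.simulate_genotypes(2 * n, m, seed=21)
cfg = eg.gxe_config([n, n], h2=[0.5, 0.5], r_g=0.3, n_snps=m, seed=22)
cohort = eg.simulate_gxe_cohort(G, cfg)
A = eg.compute_grm(G)

scan = eg.gxe_scan(cohort, A, group_col="group")
print(scan.to_frame())
```

prints

```
        term  estimate       se        p test
       h2 E1  0.474128 0.138890 6.408978e-04    a
       h2 E2  0.646602 0.118121 4.398209e-08    a
r_G (E1, E2)  0.132019 0.185096 2.740625e-06    b
```

Rows `a` are per-group SNP-heritabilities with Wald p against 0: both
groups carry significant genetic variance. Row `b` is the
cross-environment genetic correlation with Wald p against 1: the estimate
0.13 (SE 0.19) is far below 1 (p ≈ 3×10⁻⁶), correctly detecting the
simulated interaction. Estimates fluctuate around the truth (0.5/0.5 and
0.3) within their standard errors.

The same scan runs from a shell over PLINK/GCTA files:

```bash
envgreml simulate --n-per-group 350,350 --n-snps 1100 --h2 0.5 --r-g 0.3 \
         --out-prefix scratch/demo --seed 21
envgreml grm --bfile scratch/demo --out-prefix scratch/demo
envgreml gxe --grm-prefix scratch/demo --cohort scratch/demo.cohort.tsv \
         --group-col group --min-group 50
envgreml selection-theory --t1 -1 --t2 1 --h2 0.5 --mc-check 100000
```

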