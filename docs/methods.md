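# Methods

`lipidtrio` implements the analysis chain of a family-based longitudinal
study of adult lipid-associated SNPs in early childhood: a synthetic
trio-cohort generator, genotype quality control, population-stratification
PCs, unweighted genotype scores, cross-sectional and random-intercept
mixed-model association on natural-log lipid levels, and effect-size
comparison machinery (Z-tests, inverse-normal transform, variance
explained, analytic power). This note records the models, the defaults and
why, the numerical choices, and what the synthetic data do and do not show.

## The cohort model

A cohort consists of `n_families` mother–father–child trios. Parental
genotypes at each SNP are drawn independently from Hardy–Weinberg
proportions at the configured allele frequency (random mating, one
homogeneous population by default); the child receives one allele from each
parent, chosen uniformly among that parent's two alleles. Genotypes are
coded 0/1/2 as copies of the lipid-increasing allele.

Three processes corrupt the idealised cohort, each switchable:

* **Partial father genotyping** — a configurable fraction of fathers
  (default 352/544 ≈ 0.65, the study's genotyped-father fraction; its
  abstract says 324, its methods 352 — we follow the methods) have no
  genotype row; their families are mother–child duos for QC purposes.
* **Missingness** — each genotype call is independently missing at
  `genotype_missing_rate` (default 1%, consistent with call rates > 97%).
* **Non-paternity** — with probability `nonpaternity_rate` per family the
  child's *transmitted* paternal alleles are population draws while the
  recorded pedigree is left intact, so the Mendelian screen has to discover
  the substitution. Default 0; the analysis drivers use 5/352 to mirror
  the five non-biological fathers the study reports.

## The phenotype model

For each child, trait (TC, LDL-C, HDL-C, TG) and visit (ages 0, 3, 5 by
default, with measurement-age jitter drawn at the per-visit mean/SD of the
study's Table of cohort characteristics):

    ln(value) = mu(trait, visit)
              + sum of configured additive genetic effects
              + sex_effect * 1[male] + age_effect * age
              + b_child + epsilon(trait, visit)

with `b_child ~ N(0, random_intercept_sd^2)` shared over visits and
`epsilon ~ N(0, residual_sd^2)` per visit. Genetic effects are keyed by
`(predictor, visit age)` where the predictor is a SNP (per-allele effect)
or a trait genotype score (per-GS-unit effect applied to the panel score of
that trait); effects may grow with age, which is how the study's
birth → 5 y effect growth is emulated. Effects are applied to the
*complete* pre-missingness genotypes; missingness is purely observational.

`mu` is derived by lognormal moment matching from natural-scale per-visit
means/SDs (defaults from the published cohort summaries, treated as
opaque concentration units — the source prints mmol/L-scale values while
its methods say mg/dl) and is then shifted down by the expected genetic and
sex contributions so simulated per-visit means land on the published ones.
The per-visit residual SD is allocated as the remainder of the published
ln-scale variance after the random intercept and the genetic variance.

**Random-intercept defaults.** The intercept SD controls how strongly a
child's lipid ranking tracks across visits. Defaults (TC 0.13, LDL 0.19,
HDL 0.16, TG 0.27) take roughly half of each trait's smallest per-visit
ln-scale variance, matching the strong tracking of childhood lipid levels.
A caution discovered during development: the pooled mixed model includes
only a *linear* age term while the true visit baselines rise steeply from
birth to 3 y and flatten after; the unmodelled curvature acts like a
negative within-person covariance, and if the intercept variance is set
much smaller than this lack-of-fit the REML estimate collapses to its zero
boundary and the fit degrades to pooled OLS. That is a property of the
model, not a bug, and mirrors what the model would do on a real cohort
with weak tracking.

Per-visit attendance defaults to (0.84, 0.77, 0.66), reproducing the
study's per-visit analysable sample sizes (456/421/361 of 544).

## Genotype QC

* **Filters.** Samples with > 10% missing genotypes are removed first, then
  SNPs with call rate < 97% on the remaining samples; the two passes are
  iterated to a fixed point so the filter is idempotent (removing SNPs can
  push a sample's missing fraction back over threshold).
* **Hardy–Weinberg.** The 1-df goodness-of-fit chi-square against
  p², 2pq, q² at the observed allele frequency, plus a permutation p-value
  obtained by shuffling the 2n alleles into random diploid pairs B times:
  p = (1 + #{chi2_perm ≥ chi2_obs})/(1 + B). Because the statistic lives on
  the heterozygote-count lattice, exact ties carry several percent of mass
  and the naive p piles up at 1; ties are therefore broken uniformly at
  random (an iid 1e-9 jitter, far below any genuine statistic gap), the
  standard construction that makes the Monte Carlo p exactly
  discrete-uniform under the null. Founders only are tested by default, to
  avoid relatedness inflation. Bootstrap confidence intervals are not
  implemented; the permutation alone defines a valid exact test.
* **Mendelian screen.** A trio is inconsistent iff the child genotype
  cannot be one transmitted allele from each parent (equivalently
  c outside [m//2 + f//2, (m+1)//2 + (f+1)//2]); duos use the mother-only
  bound. Fathers with inconsistencies at more than 5% of their tested SNPs
  (configurable, also acceptable as an absolute count) are flagged as
  putative non-biological fathers. Pairs with a missing child or mother
  genotype are counted as untested.
* **LD pruning** is order-greedy at r² > 0.2 against previously kept SNPs;
  **proxy selection** filters candidates at r² > 0.95, prefers a coding
  non-synonymous SNP (highest r² breaking ties), else the candidate closest
  to the lead. Both operate on user-supplied tables; no LD is simulated.

## Stratification

EIGENSTRAT-style PCs: each SNP column is mean-imputed and standardized as
(g − 2p̂)/√(2p̂(1−p̂)); scores are the projections on the eigenvectors of the
individual×individual covariance of the standardized matrix (computed by
SVD), eigenvalues scaled by 1/m, signs fixed so the largest-magnitude SNP
loading is positive. PCs are computed on children and parents jointly; k
defaults to 10 as in the study's adjustment. Monomorphic SNPs are dropped
with a warning.

## Genotype scores

Unweighted sums of risk-allele counts over each trait panel (69 TC, 59
LDL-C, 73 HDL-C, 40 TG in the default generator, overlapping panels).
Missing genotypes are mean-imputed per SNP over all genotyped individuals
(children-only imputation available via `impute_on`).

## Association models

Traits are natural-log transformed. Cross-sectional: per-visit OLS of
ln(trait) on the predictor + sex + age + PC1..PC10, t-based two-sided p.
Longitudinal: random-intercept LMM over all visits fitted by REML
(statsmodels MixedLM, default BFGS optimizer with a Powell retry — the
L-BFGS path in statsmodels fails with singular matrices on these designs),
Wald normal p for the predictor's fixed effect; intercept and residual
variances exposed for diagnostics. A boundary fit (intercept variance at
zero, or a stalled optimizer with the variance ratio below 1%) falls back
to pooled OLS with a warning. Optional mother/father genotype covariates
implement the parental-adjustment variant; off by default. Collinear design
columns raise an error naming the aliased columns; constant covariates
(e.g. age without jitter at a single visit) are dropped with a warning.
The Bonferroni threshold counts markers × measurement times
(0.05/(158 × 3) = 1.05e-4 at the study scale).

## Comparison machinery

* **Z-test**: z = (β_a − β_b)/√(se_a² + se_b²). The default p is
  1 − Φ(|z|): although the published comparison describes its p-values as
  two-tailed, every printed p in the bundled table equals the one-sided
  upper tail (all 21 complete rows reproduce to printed precision under
  this convention, none under the two-sided one); `two_sided=True` gives
  the doubled version.
* **Inverse-normal transform**: Φ⁻¹((rank − 0.5)/n) with average ranks for
  ties — the consortium-style rank transform used to put child and adult
  effects on a common trait scale (offset 0.5, not Blom's 3/8).
* **Variance explained**: theoretical Σβ²·2·MAF·(1−MAF) from summary
  statistics as a fraction of trait variance; empirical as the adjusted R²
  of the joint OLS of covariate-residualized ln(trait) on all panel SNPs,
  floored at zero, with a GCV-chosen ridge fallback when the design is
  rank-deficient or undersized. This joint-OLS estimator replaces
  GREML-with-GRM: at panel sizes (40–73) far below n it is a consistent
  estimator of the same quantity for unrelated individuals; relatedness
  handling is out of scope.
* **Analytic power**: two-sided test of one additive genotype term with
  noncentrality λ = n·β²·2·MAF·(1−MAF)/σ², power = P(|N(√λ,1)| > z_{1−α/2});
  `min_detectable_beta` inverts it. The study's "80% power, detectable
  β ≈ 0.08" statement left α, σ and the model unstated; with σ set to the
  mean five-year ln-scale SD (≈0.27) and α = 0.05, the worst case over
  MAF 10–90% at n = 361 is ≈ 0.095 — the same order, reported as a
  consistency check only.
* **Cross-age comparison** applies the naive Z-test to per-visit estimates;
  the overlap of individuals between visits is ignored (as in the source
  procedure) and every result carries a note saying so.

## What the synthetic data do not show

SNPs are simulated without LD, population structure (unless the
two-subpopulation mode is used), genotyping batch effects, or
assay/measurement error beyond the lognormal residual; phenotype attrition
is independent of phenotype and genotype (missing completely at random),
whereas real cohort dropout may be informative. Passing tests demonstrate
the estimators are correct and calibrated under the assumed
data-generating process, not that the model assumptions hold in any real
cohort. The original cohort's per-SNP coefficient tables and the
child/adult variance percentages are not reproducible without the raw
cohort and consortium files; the published child-vs-adult Z table is
reproducible from its printed betas/SEs and is recomputed exactly.

## Problem sizes

The bundled drivers and checks use: 544 families × 158 SNPs for the
study-scale cohort; 100 replicates of 500 trios × 3 visits for mixed-model
recovery; 1000 replicates of 456 children for type-I calibration; 1000
SNPs at n = 500 with B = 999 for permutation uniformity; 300 trios × 120
SNPs at 2% non-paternity for the Mendelian screen; n = 10⁶ Monte Carlo for
the 40-SNP variance oracle.
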