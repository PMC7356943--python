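# Methods

This note documents the models and procedures `microgrs` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## Genetic risk score construction

The score is learned from a training cohort in three stages
(`microgrs.grs.GRSBuilder`):

1. **Screen.** Per SNP, a tie-corrected Kruskal–Wallis test of BMI across
   the observed genotype categories (absence of the minor allele, one
   copy, two copies). SNPs with p < `alpha1` (default 0.20 — deliberately
   lenient, this stage only shortlists candidates) continue; SNPs without
   at least two genotype groups of at least two subjects are flagged
   untestable.
2. **Code.** Genotype groups are ordered by median BMI (the median, not
   the mean, for coherence with the rank tests). Adjacent groups whose
   pairwise Mann–Whitney p is ≥ `merge_alpha` (default 0.05) are deemed
   to have similar effects and are merged into a single category. If all
   groups merge, the SNP has no valid split and is excluded. If three
   separable groups remain, the binary split with the stronger two-group
   Mann–Whitney separation is used. The side with the higher median BMI is
   the **risk** category; by construction, median BMI(risk) ≥ median
   BMI(non-risk) on the training data.
3. **Confirm and filter.** A two-group Mann–Whitney test on the binary
   coding retains SNPs with p < `alpha2` (default 0.10). Codings where
   either category holds fewer than `min_frac` (default 10%) of the
   subjects genotyped at that SNP are dropped as low-count. Finally,
   retained codings are pruned for collinearity: among pairs of 0/1 risk
   indicators with |Pearson r| > `collinearity_r` (default 0.8), the SNP
   with the larger stage-3 p is dropped, repeatedly, starting from the
   most correlated pair.

**Scoring semantics.** The GRS is the number of retained loci at which a
subject's genotype lies in the risk category — a per-locus binary
indicator sum with maximum equal to the number of retained loci, *not* an
allele count. A subject homozygous for risk genotypes at six of ten loci
scores 6, not 12. This is forced by the coding itself: risk categories are
genotype sets (e.g. "GG+CC vs GC"), which have no meaningful allele dose.

Missing genotypes exclude a subject from that SNP's tests, and from the
GRS entirely if any retained locus is missing (no imputation). The
high/low GRS group split is at the population mean, ties assigned high.

The package also carries the published 10-SNP adiposity panel
(`microgrs.panel.published_grs_panel`) as data, for scoring worked
examples; one row of the published listing names the same heterozygote on
both sides of its partition, which is resolved to the only genotype not
named non-risk (see the module docstring). The pipeline itself never uses
the published panel: codings are always re-learned from the input cohort.

## Microbiome preparation

Count matrices are families × samples with library size = column sum.

* **Filtering** keeps families present in ≥ 10% of samples with total
  count ≥ 10 (both configurable; the source analyses do not state their
  thresholds, so these common amplicon defaults are used and logged).
* **Relative abundance** is on a 0–100 percent scale, because the
  interaction models and predicted curves evaluate abundance at values
  like 5 and 15.
* **CSS normalization** divides each sample by the sum of its counts up to
  a chosen quantile of its nonzero-count distribution and rescales by the
  median factor, keeping the output count-like. `quantile=1.0` collapses
  to total-sum scaling. `quantile="auto"` runs a simplified stability
  scan: the first grid quantile (step 0.05) at which the median
  per-sample quantile value changes by more than 10% relative to the
  previous grid point, falling back to 0.5; a warning is emitted when the
  scan settles below 0.25. This is a deliberately simple variant of the
  reference heuristic; analyses that need an exact match should pass a
  fixed quantile.
* **Diversity.** Shannon H = −Σ p ln p in nats (some tools use log2;
  multiply by 1/ln 2 to convert), Chao1 in its bias-corrected form
  S_obs + F₁(F₁−1)/(2(F₂+1)) so samples without doubletons are defined,
  Bray–Curtis via the standard rank-based distance. Trait associations use
  Spearman correlations, overall and within sex strata.

## Differential abundance

* **LDA effect size (LEfSe-style).** Features are rescaled to sum 10⁶ per
  sample; families passing the Kruskal–Wallis screen (p < 0.05) receive a
  bootstrapped (30 rounds) one-dimensional Fisher discriminant effect —
  the class-mean difference along the regularized discriminant direction,
  the pooled within-class variance being regularized by 1e-6 × its own
  scale to avoid singularities — and the score log10(10 + |effect|/2),
  thresholded at 2.0. Only the two-class core is implemented: no subclass
  stage, because the analyses this package supports are plain two-group
  comparisons; scores are therefore not numerically identical to the
  Galaxy tool. Bootstrap resampling order is canonicalized by sample
  membership so scores are invariant under relabeling the classes. Per
  tool convention, no FDR correction is applied at this stage.
* **Zero-inflated Gaussian (ZIG).** Per family, an EM fit of a mixture of
  a point mass at zero, with sample-specific weight from a logistic model
  on log library size (the method's core idea; no further zero-model
  covariates, and no moderation of variances), and a Gaussian on
  log2(CSS count + 1) with mean = intercept + group effect. EM iterates to
  a log-likelihood change < 1e-8 (at most 100 iterations; non-convergence
  is flagged and the last iterate reported), and the log-likelihood is
  non-decreasing by construction. The group coefficient is z-tested with
  weights equal to the posterior non-zero membership; q-values are
  Benjamini–Hochberg across tested families. On zero-free data the model
  collapses exactly to a two-sample z-test on the log2 CSS values with ML
  pooled variance. All-zero families are skipped with a flag.
* **Random forest.** Per repeat (10 by default), a stratified 70/30 split;
  500 trees on the training part; feature importance as mean decrease in
  accuracy (MDA) by Breiman-style out-of-bag permutation (per tree, each
  feature used by that tree is permuted among the tree's out-of-bag
  samples; unused features contribute an exact zero), and the held-out 30%
  scored by ROC AUC. Families are ranked by mean MDA across repeats.

## Interaction models

OLS of BMI on abundance, GRS, their product, age, physical activity
(METs), and energy intake (kcal); sex enters the pooled fit only —
stratified fits drop the column and the out-of-stratum subjects. Standard
errors use the unbiased residual variance; adjusted R² =
1 − (1−R²)(n−1)/(n−p−1). Rank-deficient designs raise an error naming the
collinear columns. Predicted-BMI curves hold the remaining covariates at
their fit-sample means (the conditioning used for published curves is not
stated; means are the conventional choice) and evaluate a GRS grid at
fixed abundance values; by linear-model algebra the slope gap between
curves at abundances a₁ < a₂ is exactly (a₂−a₁) × the interaction
coefficient.

WHO BMI classes as half-open intervals: normalweight < 25, overweight
[25, 30), obese ≥ 30 (the verbal cutoffs "< 24.9 / < 29.9 / > 30" leave
gaps; the standard intervals close them), with an optional binary merge
into normalweight vs overweight+obese.

## Synthetic cohort generator

The generator (`microgrs.simulate`) emulates the statistical structure the
analyses assume, not any particular dataset:

* **Genotypes.** 95 biallelic SNPs drawn i.i.d. under Hardy–Weinberg
  proportions (no linkage disequilibrium), 10 of them causal under mixed
  dominance patterns (dominant, recessive, heterozygote-disadvantage,
  additive) with effects of ~1–2 kg/m² — magnitudes consistent with the
  genotype-group BMI contrasts reported for such panels, which never print
  per-SNP effects. Causal minor-allele frequencies are 0.35–0.5 so every
  risk category is common enough to survive the low-count filter.
* **Covariates.** Cohort defaults mirror the modeled study population:
  n = 360, 70% female (251/360), age 44.8 ± 10 y (truncated at 18), METs
  25 ± 15 (truncated at 0), energy 2907 ± 900 kcal.
* **Microbiome.** 64 families; zero-inflated log-normal intensities
  renormalized per sample and scaled to a negative-binomial library size
  (mean 60 000, dispersion 10), rounded to integer counts. The non-focal
  profile is a power law (most abundant family ~20%); the focal family
  (Prevotellaceae) sits at ~8% mean relative abundance with log-sd 0.7, so
  the 5%/15% evaluation points of the predicted curves are within its
  range. Rare families get zero-inflation up to 0.7.
* **BMI.** baseline + Σ per-SNP effect × dosage + β_sex × (focal % ×
  true risk count) + Gaussian noise (sd 3.5). The interaction defaults are
  female 0.10, male 0.0 kg/m² per (percent abundance × GRS unit) — the
  published women-stratum estimate planted as truth, on the percent scale
  because that is the scale the published curves evaluate. The baseline
  (21.0) was set once so the WHO class fractions come out near the
  modeled population's 18/30/52 split under the default genetic and
  interaction structure. The recorded `true_grs` is the planted per-locus
  risk-indicator sum.

**What passing tests do and do not show.** The generator draws independent
SNPs, log-normal families without inter-family correlation, and Gaussian
BMI noise. Real cohorts have LD, compositional correlation structure,
batch effects and non-Gaussian outcomes; parameter-recovery results here
certify the estimators against the model they assume, not robustness to
those violations. The learned GRS is a noisy proxy of the planted risk
count, so interaction estimates using it are attenuated relative to the
planted 0.10 (the recovery analyses therefore fit against the recorded
true risk count).

## Numerical conventions

* All rank tests use midranks with tie correction; p-values are
  two-sided. The Mann–Whitney normal approximation omits the continuity
  correction so that on two groups it coincides exactly with the 1-df
  Kruskal–Wallis chi-square p.
* Exact permutation p-values are used automatically for small samples
  (pooled n ≤ 10 for Kruskal–Wallis, ≤ 14 for Mann–Whitney, ≤ 8 for
  Spearman) and can be forced with `method="exact"`; comparisons use a
  1e-12 slack so permutations tied with the observed statistic count as
  at least as extreme.
* Fully tied data yield p = 1 (statistic 0); constant inputs to Spearman
  are flagged degenerate with NaN rho.
* The Hardy–Weinberg test is the 1-df chi-square against expected counts
  from the sample allele frequency; monomorphic samples return 0 / p = 1.
* Determinism: every stochastic entry point takes a seed; the pipeline
  derives per-stage child seeds from the run seed via `SeedSequence`, and
  reruns with the same manifest are byte-identical.

## Problem sizes used in the test and acceptance suites

Replicate counts and forest sizes in the automated suites are the
package's own choices to keep the checks sharp but cheap: 200 replicate
cohorts for interaction recovery and null-screen calibration, 25 seeds for
ZIG fold-change recovery, 10 seeds with 100-tree / 5-repeat forests for
the joint-discovery property (the pipeline default remains 500 trees × 10
repeats), and brute-force enumeration oracles at n ≤ 9.

## Known limitations

* The ZIG zero-model uses log library size as its only covariate and
  plain ML EM; tools that moderate variances across features will give
  smaller standard errors on small samples.
* The LEfSe-style score is a two-class reimplementation, not a wrapper of
  the Galaxy tool; thresholds are comparable, exact scores are not.
* The CSS "auto" quantile is a simplified stability scan (see above).
* No linkage disequilibrium, haplotypes, or dietary-pattern structure in
  the generator; energy intake is a single total.
* Diversity indices are computed on raw counts (the usual convention);
  rarefaction is out of scope.
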