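# microgrs

Genetic risk scores, gut-microbiome statistics and sex-stratified
gene–microbiome interaction models for adiposity cohorts.

## The problem

Host genetics and the gut microbiome both shape body-mass index (BMI), and
their interplay may explain inter-individual differences that neither
explains alone. `microgrs` implements, as a tested and reusable pipeline,
the analysis pattern used in cohort studies of this interplay:

1. **Data-driven genetic risk score (GRS).** Starting from a panel of
   obesity-related biallelic SNPs, each SNP's three genotype categories are
   screened against BMI with a Kruskal–Wallis test (keep p < 0.20), recoded
   into a binary *risk / non-risk* partition by Mann–Whitney post-hoc tests
   (genotypes with similar effects are merged; the higher-median-BMI side is
   the risk category), confirmed with a two-group Mann–Whitney test
   (p < 0.10), and filtered for low counts (< 10% of subjects in either
   category) and collinearity. The GRS of a subject is the **number of
   retained loci carrying the risk genotype** — an indicator sum, so a
   subject with risk genotypes at 6 of 10 retained loci scores 6.
2. **Family-level microbiome statistics.** Prevalence/total-count
   filtering, percent relative abundance, cumulative sum scaling (CSS),
   Shannon (nats) and bias-corrected Chao1 diversity, Bray–Curtis
   dissimilarity, and sex-stratified Spearman associations of diversity
   with traits.
3. **Two-group differential abundance** between BMI classes (WHO
   normalweight vs overweight+obese) or GRS groups (split at the population
   mean): Kruskal–Wallis + bootstrapped linear-discriminant effect sizes
   (LEfSe-style log10 scores, threshold 2.0), zero-inflated Gaussian (ZIG)
   regression on CSS-normalized log2 counts with Benjamini–Hochberg FDR,
   and random-forest importance (mean decrease in accuracy from out-of-bag
   permutation, 500 trees, 10 repeats, 70/30 validation with ROC AUC).
4. **Interaction regressions.** OLS models
   `BMI ~ abundance + GRS + abundance×GRS + age + METs + energy (+ sex)`,
   fitted pooled and stratified by sex, with predicted-BMI curves over the
   GRS range at fixed abundance values (e.g. 5% and 15%).

Because cohort genotype/phenotype data of this kind are rarely public, the
package ships a first-class synthetic cohort generator
(`microgrs.simulate`) that emulates the statistical structure the analysis
assumes: 95 SNPs in Hardy–Weinberg equilibrium with ~10 truly
BMI-associated loci under mixed dominance patterns, a 64-family
zero-inflated log-normal count matrix with variable library size, and a
female-specific (Prevotellaceae × GRS) interaction on BMI.

## Worked example

```python
from microgrs import (GRSBuilder, split_by_mean, relative_abundance,
                      interaction_model)
from microgrs.simulate import CohortConfig, simulate_cohort

cohort, counts, specs = simulate_cohort(CohortConfig(n_subjects=360, seed=8))
geno = cohort[[s.snp_id for s in specs]]

builder = GRSBuilder().fit(geno, cohort["bmi"])
grs = builder.transform(geno)
prev = relative_abundance(counts).loc["Prevotellaceae"]
prev.index = cohort.index
for stratum in ("female", "male"):
    fit = interaction_model(cohort["bmi"], prev, grs,
                            cohort[["age", "mets", "energy", "sex"]],
                            stratum=stratum)
    r = fit["abundance_x_grs"]
    print(f"{stratum}: beta={r['beta']:+.3f} +/- {r['se']:.3f} "
          f"p={r['pvalue']:.3f} n={fit.n}")
```

prints

```
female: beta=+0.138 +/- 0.030 p=0.000 n=270
male: beta=-0.009 +/- 0.046 p=0.839 n=90
```

i.e. on this synthetic cohort the learned 9-SNP score interacts with
Prevotellaceae abundance in women (each percent of abundance adds ~0.14
kg/m² of BMI per GRS point) but not in men — the sex-specific pattern the
generator plants (women-only interaction of 0.10 kg/m² per percent × GRS
unit; the learned-score estimate fluctuates around it across seeds because
the score is a noisy proxy for the planted risk count).

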