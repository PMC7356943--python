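"""Synthetic adiposity-cohort generator.

Emulates the statistical structure the downstream analyses assume: biallelic
SNP genotypes drawn under Hardy-Weinberg equilibrium with a handful of truly
BMI-associated loci under mixed dominance patterns, a zero-inflated
log-normal family-level 16S count matrix with variable library size, Table-1
style covariates (age, physical activity in METs, energy intake) and a BMI
generated additively from the planted SNP effects plus a sex-specific
(focal-family relative abundance x genetic risk score) interaction.

Every entry point is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SNPSpec",
    "CohortConfig",
    "MicrobiomeConfig",
    "EFFECT_MODELS",
    "default_snp_panel",
    "default_microbiome_config",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_microbiome",
    "simulate_bmi",
    "simulate_cohort",
    "friedewald_ldl",
]

# dosage of the risk effect per genotype category (hom-major, het, hom-minor)
EFFECT_MODELS = {
    "none": (0.0, 0.0, 0.0),
    "additive": (0.0, 0.5, 1.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
    "heterozygote-disadvantage": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic SNP: alleles, minor-allele frequency and planted effect."""

    snp_id: str
    alleles: tuple[str, str]  # (major, minor)
    maf: float
    effect_model: str = "none"
    effect_size: float = 0.0  # BMI shift (kg/m^2) at full dosage

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must lie in [0, 0.5], got {self.maf}")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"{self.snp_id}: unknown effect model {self.effect_model!r}")
        if (self.effect_model == "none") != (self.effect_size == 0.0):
            raise ValueError(
                f"{self.snp_id}: effect_size must be 0 iff effect_model is 'none'"
            )

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """Category labels (hom-major, het, hom-minor)."""
        a, b = self.alleles
        return (a + a, a + b, b + b)

    def dosages(self) -> dict[str, float]:
        return dict(zip(self.genotypes, EFFECT_MODELS[self.effect_model]))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings (defaults mirror the study population)."""

    n_subjects: int = 360
    female_fraction: float = 251 / 360
    age_mean: float = 44.8
    age_sd: float = 10.0
    mets_mean: float = 25.0
    mets_sd: float = 15.0
    energy_mean: float = 2907.0
    energy_sd: float = 900.0
    bmi_baseline: float = 21.0
    bmi_noise_sd: float = 3.5
    interaction_beta_female: float = 0.10  # kg/m^2 per (% abundance x GRS unit)
    interaction_beta_male: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        for name in ("age_sd", "mets_sd", "energy_sd", "bmi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MicrobiomeConfig:
    """Family-level count-matrix generator settings.

    ``families`` holds one row per family with columns ``family``,
    ``log_mean`` (log of the mean relative intensity), ``log_sd`` and
    ``zero_inflation``.  Library sizes are negative-binomial with the given
    mean and dispersion (size parameter).
    """

    families: pd.DataFrame = field(default_factory=lambda: _default_family_table())
    library_size_mean: float = 60000.0
    library_size_dispersion: float = 10.0
    focal_family: str = "Prevotellaceae"

    def __post_init__(self):
        required = {"family", "log_mean", "log_sd", "zero_inflation"}
        if not required.issubset(self.families.columns):
            raise ValueError(f"families table must have columns {sorted(required)}")
        zi = self.families["zero_inflation"].to_numpy(float)
        if np.any(zi < 0) or np.any(zi >= 1):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.focal_family not in set(self.families["family"]):
            raise ValueError(f"focal family {self.focal_family!r} missing from table")

    @property
    def n_families(self) -> int:
        return len(self.families)


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A"), ("G", "T"), ("A", "C")]

# planted causal structure: mixed dominance patterns, contrasts of ~1-2 kg/m^2
_CAUSAL_MODELS = [
    ("dominant", 1.6),
    ("recessive", 1.4),
    ("heterozygote-disadvantage", 1.2),
    ("dominant", 1.0),
    ("additive", 1.5),
    ("dominant", 1.1),
    ("recessive", 1.3),
    ("heterozygote-disadvantage", 0.9),
    ("additive", 1.2),
    ("dominant", 1.0),
]


def default_snp_panel(n_snps: int = 95, n_causal: int = 10) -> list[SNPSpec]:
    """Deterministic 95-SNP panel with ``n_causal`` BMI-associated loci.

    Causal loci carry moderate minor-allele frequencies (0.35-0.5) so that
    every genotype risk category is common enough to survive the low-count
    filter of the score construction.
    """
    if not 0 <= n_causal <= n_snps:
        raise ValueError("need 0 <= n_causal <= n_snps")
    specs = []
    for i in range(n_snps):
        alleles = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        if i < n_causal:
            model, effect = _CAUSAL_MODELS[i % len(_CAUSAL_MODELS)]
            maf = 0.35 + 0.015 * i
        else:
            model, effect = "none", 0.0
            maf = 0.10 + 0.40 * ((i * 7) % n_snps) / max(n_snps - 1, 1)
        specs.append(
            SNPSpec(f"snp{i + 1:03d}", alleles, round(min(maf, 0.5), 4), model, effect)
        )
    return specs


def _default_family_table(n_families: int = 64, focal: str = "Prevotellaceae") -> pd.DataFrame:
    """Power-law family profile with the focal family at ~8% mean abundance."""
    ranks = np.arange(1, n_families)
    weights = (92.0 / np.sum(1.0 / ranks)) / ranks  # non-focal, sums to ~92
    names = [focal] + [f"Family{r:02d}" for r in ranks]
    w = np.concatenate([[8.0], weights])
    zi = np.where(w >= 1.0, 0.0, np.clip(0.7 * (1.0 - w), 0.0, 0.7))
    return pd.DataFrame(
        {
            "family": names,
            "log_mean": np.log(w),
            "log_sd": np.where(np.array(names) == focal, 0.7, 0.8),
            "zero_inflation": zi,
        }
    )


def default_microbiome_config(n_families: int = 64, focal_family: str = "Prevotellaceae") -> MicrobiomeConfig:
    return MicrobiomeConfig(
        families=_default_family_table(n_families, focal_family),
        focal_family=focal_family,
    )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(specs: list[SNPSpec], n: int, seed: int) -> pd.DataFrame:
    """Draw genotype strings per subject under HWE, independently per SNP."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    data = {}
    for spec in specs:
        p = spec.maf
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        data[spec.snp_id] = rng.choice(np.array(spec.genotypes), size=n, p=probs)
    index = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(data, index=index)


def simulate_covariates(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Sex, age, METs and energy intake; truncated at plausibility bounds
    (age >= 18, METs >= 0, energy > 0)."""
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_subjects
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")

    def trunc_normal(mean, sd, lower):
        if sd == 0:
            return np.full(n, float(mean))
        a = (lower - mean) / sd
        return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    index = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(
        {
            "sex": sex,
            "age": trunc_normal(config.age_mean, config.age_sd, 18.0),
            "mets": trunc_normal(config.mets_mean, config.mets_sd, 0.0),
            "energy": trunc_normal(config.energy_mean, config.energy_sd, 1.0),
        },
        index=index,
    )


def simulate_microbiome(config: MicrobiomeConfig, n: int, seed: int) -> pd.DataFrame:
    """Zero-inflated log-normal family count matrix (families x samples).

    Per cell: zero with the family's zero-inflation probability, otherwise a
    log-normal intensity; intensities are renormalized per sample and scaled
    to a negative-binomial library size, then rounded to integer counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    fam = config.families
    k = len(fam)
    mu = fam["log_mean"].to_numpy(float)[:, None]
    sd = fam["log_sd"].to_numpy(float)[:, None]
    zi = fam["zero_inflation"].to_numpy(float)[:, None]

    present = rng.random((k, n)) >= zi
    intensity = np.exp(rng.normal(mu, sd, size=(k, n))) * present
    totals = intensity.sum(axis=0)
    empty = totals == 0
    if np.any(empty):  # pathological configs: assign the library to the top family
        top = int(np.argmax(mu.ravel()))
        intensity[top, empty] = 1.0
        totals = intensity.sum(axis=0)

    p_nb = config.library_size_dispersion / (
        config.library_size_dispersion + config.library_size_mean
    )
    libsize = rng.negative_binomial(config.library_size_dispersion, p_nb, size=n) + 1
    counts = np.rint(intensity / totals * libsize).astype(np.int64)

    samples = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(counts, index=pd.Index(fam["family"], name="family"), columns=samples)


def simulate_bmi(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    focal_relabund,
    specs: list[SNPSpec],
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate BMI from planted SNP effects and the sex-specific
    (focal abundance x true GRS) interaction; returns bmi and true_grs.

    BMI = baseline + sum_j effect_j * dosage_j
          + beta_sex * (focal relative abundance in % x true GRS) + noise.
    ``true_grs`` counts causal loci with positive dosage.
    """
    focal = pd.Series(np.asarray(focal_relabund, dtype=float), index=genotypes.index) \
        if not isinstance(focal_relabund, pd.Series) else focal_relabund.astype(float)
    if not (genotypes.index.equals(covariates.index) and genotypes.index.equals(focal.index)):
        raise ValueError("genotypes, covariates and focal_relabund must share subjects")
    rng = _rng(config.seed if seed is None else seed)
    n = len(genotypes)

    effect = np.zeros(n)
    indicator_sum = np.zeros(n, dtype=int)
    for spec in specs:
        if spec.effect_model == "none":
            continue
        if spec.snp_id not in genotypes.columns:
            raise ValueError(f"causal SNP {spec.snp_id} missing from genotype matrix")
        dosage = genotypes[spec.snp_id].map(spec.dosages())
        if dosage.isna().any():
            bad = genotypes.index[dosage.isna()][0]
            raise ValueError(f"unknown genotype for {spec.snp_id} at subject {bad}")
        effect += spec.effect_size * dosage.to_numpy(float)
        indicator_sum += (dosage.to_numpy(float) > 0).astype(int)

    beta = np.where(
        covariates["sex"].to_numpy() == "female",
        config.interaction_beta_female,
        config.interaction_beta_male,
    )
    bmi = (
        config.bmi_baseline
        + effect
        + beta * focal.to_numpy() * indicator_sum
        + rng.normal(0.0, config.bmi_noise_sd, size=n)
    )
    return pd.DataFrame({"bmi": bmi, "true_grs": indicator_sum}, index=genotypes.index)


def simulate_cohort(
    config: CohortConfig | None = None,
    micro_config: MicrobiomeConfig | None = None,
    specs: list[SNPSpec] | None = None,
    seed: int | None = None,
):
    """Full synthetic cohort: returns (cohort table, count matrix, specs).

    The cohort table carries subject_id (index), sex, age, mets, energy,
    bmi, true_grs and one genotype column per SNP.  The count matrix is
    families x samples with sample ids equal to subject ids.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    micro_config = micro_config or default_microbiome_config()
    specs = specs if specs is not None else default_snp_panel()

    ss = np.random.SeedSequence(config.seed)
    s_geno, s_cov, s_micro, s_bmi = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    genotypes = simulate_genotypes(specs, config.n_subjects, s_geno)
    covariates = simulate_covariates(config, s_cov)
    counts = simulate_microbiome(micro_config, config.n_subjects, s_micro)
    counts.columns = genotypes.index.rename("sample_id")

    libsize = counts.sum(axis=0)
    focal = 100.0 * counts.loc[micro_config.focal_family] / libsize
    focal.index = genotypes.index

    outcome = simulate_bmi(genotypes, covariates, focal, specs, config, s_bmi)
    cohort = pd.concat([covariates, outcome, genotypes], axis=1)
    return cohort, counts, specs


def friedewald_ldl(tc, hdl, tg):
    """LDL cholesterol (mg/dL) by the Friedewald equation: TC - HDL - TG/5.

    Inputs are mg/dL; the formula is unreliable above 400 mg/dL
    triglycerides, which triggers a warning.  Negative inputs are rejected.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("cholesterol and triglyceride values must be non-negative")
    if np.any(tg > 400):
        warnings.warn(
            "Friedewald equation is unreliable for triglycerides > 400 mg/dL",
            UserWarning,
            stacklevel=2,
        )
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out
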