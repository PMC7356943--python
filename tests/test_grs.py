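"""GRS construction: coding derivation, filtering, scoring semantics."""

import numpy as np
import pandas as pd
import pytest

from microgrs import (
    GRSBuilder,
    RiskCoding,
    compute_grs,
    confirm_and_filter,
    derive_risk_coding,
    kw_screen,
    published_grs_panel,
    split_by_mean,
)
from microgrs.simulate import CohortConfig, default_snp_panel, simulate_cohort

from conftest import genotype_series


def _bmi_for(groups, rng, sds=1.0):
    """BMI vector with one normal blob per genotype group."""
    parts = [rng.normal(mu, sds, size=n) for mu, n in groups]
    values = np.concatenate(parts)
    idx = pd.Index([f"S{i:03d}" for i in range(len(values))], name="subject_id")
    return pd.Series(values, index=idx, name="bmi")


def test_coding_merges_indistinguishable_high_groups(rng):
    """Medians ~28/30/30 with the two high groups alike -> they form the
    risk category together (the het stays non-risk)."""
    geno = genotype_series(["GC", "GG", "CC"], [40, 30, 30])
    bmi = _bmi_for([(28, 40), (30.0, 30), (30.1, 30)], rng)
    coding = derive_risk_coding(geno, bmi)
    assert coding.risk_genotypes == {"GG", "CC"}
    assert coding.nonrisk_genotypes == {"GC"}


def test_coding_heterozygote_advantage_shape(rng):
    """Het lowest, homozygotes alike -> coding shape 'AG | GG+AA'."""
    geno = genotype_series(["AG", "GG", "AA"], [40, 30, 30])
    bmi = _bmi_for([(27, 40), (30.0, 30), (30.05, 30)], rng)
    coding = derive_risk_coding(geno, bmi)
    assert coding.nonrisk_genotypes == {"AG"}
    assert coding.risk_genotypes == {"GG", "AA"}


def test_coding_identical_groups_excluded(rng):
    geno = genotype_series(["AA", "AG", "GG"], [30, 30, 30])
    bmi = _bmi_for([(30, 30), (30, 30), (30, 30)], rng)
    coding = derive_risk_coding(geno, bmi)
    assert coding.excluded and coding.exclusion_reason == "nonsignificant"


def test_coding_risk_side_has_higher_median(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        geno = genotype_series(["AA", "AG", "GG"], [50, 40, 30])
        bmi = _bmi_for([(28, 50), (30, 40), (32, 30)], r)
        coding = derive_risk_coding(geno, bmi)
        if coding.excluded:
            continue
        risk = bmi[geno.isin(coding.risk_genotypes)]
        nonrisk = bmi[geno.isin(coding.nonrisk_genotypes)]
        assert risk.median() >= nonrisk.median()


def test_kw_screen_flags_untestable_and_constant(rng):
    geno = pd.DataFrame(
        {
            "mono": ["AA"] * 30,
            "ok": ["AA"] * 10 + ["AG"] * 10 + ["GG"] * 10,
        },
        index=pd.Index([f"S{i:03d}" for i in range(30)]),
    )
    bmi = pd.Series(rng.normal(30, 3, 30), index=geno.index)
    scr = kw_screen(geno, bmi)
    assert not scr.loc["mono", "testable"]
    assert scr.loc["ok", "testable"]
    constant = pd.Series(np.full(30, 25.0), index=geno.index)
    assert kw_screen(geno[["ok"]], constant).loc["ok", "pvalue"] == 1.0


def test_low_count_category_excluded(rng):
    geno = genotype_series(["AA", "GG"], [95, 5])
    bmi = _bmi_for([(28, 95), (40, 5)], rng)
    coding = derive_risk_coding(geno, bmi)
    report = confirm_and_filter([coding], geno.to_frame(), bmi)
    assert report.retained == []
    assert report.coding("snpX").exclusion_reason == "low-count"


def test_collinear_codings_pruned(rng):
    """Two SNPs with identical coded indicators -> exactly one retained."""
    g1 = genotype_series(["AA", "GG"], [50, 50], name="snpA")
    g2 = genotype_series(["CC", "TT"], [50, 50], name="snpB")
    bmi = _bmi_for([(27, 50), (33, 50)], rng)
    genotypes = pd.concat([g1, g2], axis=1)
    codings = [
        derive_risk_coding(genotypes[c], bmi, snp_id=c) for c in genotypes.columns
    ]
    report = confirm_and_filter(codings, genotypes, bmi)
    assert len(report.retained) == 1
    dropped = ({"snpA", "snpB"} - set(report.retained)).pop()
    assert report.coding(dropped).exclusion_reason == "collinearity"


def test_grs_is_indicator_sum_not_allele_count():
    """A subject homozygous for risk at 6 of 10 loci scores 6, not 12."""
    panel = published_grs_panel()
    geno = {}
    for i, c in enumerate(panel):
        if i < 6:
            hom = [g for g in sorted(c.risk_genotypes) if g[0] == g[1]]
            geno[c.snp_id] = hom[0] if hom else sorted(c.risk_genotypes)[0]
        else:
            geno[c.snp_id] = sorted(c.nonrisk_genotypes)[0]
    frame = pd.DataFrame([geno], index=["subj1"])
    assert compute_grs(panel, frame).loc["subj1"] == 6


def test_grs_bounds_and_additivity():
    panel = published_grs_panel()
    all_risk = pd.DataFrame(
        [{c.snp_id: sorted(c.risk_genotypes)[0] for c in panel}], index=["hi"]
    )
    none_risk = pd.DataFrame(
        [{c.snp_id: sorted(c.nonrisk_genotypes)[0] for c in panel}], index=["lo"]
    )
    assert compute_grs(panel, all_risk).loc["hi"] == 10
    assert compute_grs(panel, none_risk).loc["lo"] == 0
    # removing one locus lowers each score by exactly that locus's indicator
    reduced = compute_grs(panel[1:], all_risk)
    assert reduced.loc["hi"] == 9


def test_grs_unknown_genotype_is_named():
    panel = published_grs_panel()
    frame = pd.DataFrame(
        [{c.snp_id: sorted(c.risk_genotypes)[0] for c in panel}], index=["s1"]
    )
    frame.loc["s1", panel[0].snp_id] = "XX"
    with pytest.raises(ValueError, match=panel[0].snp_id):
        compute_grs(panel, frame)


def test_grs_missing_genotype_excludes_subject():
    panel = published_grs_panel()
    frame = pd.DataFrame(
        [
            {c.snp_id: sorted(c.risk_genotypes)[0] for c in panel},
            {c.snp_id: sorted(c.risk_genotypes)[0] for c in panel},
        ],
        index=["full", "holey"],
    )
    frame.loc["holey", panel[3].snp_id] = "."
    grs, excluded = compute_grs(panel, frame, return_excluded=True)
    assert excluded == ["holey"]
    assert list(grs.index) == ["full"]


def test_split_by_mean_rules():
    s = pd.Series({"a": 5, "b": 6, "c": 7})
    labels = split_by_mean(s)
    assert labels.tolist() == ["low", "high", "high"]  # ties at the mean go high
    s2 = pd.Series({"a": 0, "b": 10})
    assert split_by_mean(s2).tolist() == ["low", "high"]
    shifted = split_by_mean(s + 3)
    pd.testing.assert_series_equal(labels, shifted)
    with pytest.warns(UserWarning):
        split_by_mean(pd.Series({"a": 4, "b": 4}))


def test_selection_invariant_under_input_permutations():
    cohort, _, specs = simulate_cohort(CohortConfig(n_subjects=200, seed=21),
                                       specs=default_snp_panel(n_snps=15, n_causal=5))
    geno = cohort[[s.snp_id for s in specs]]
    bmi = cohort["bmi"]
    base = GRSBuilder().fit(geno, bmi).retained_snps_
    rng = np.random.default_rng(0)
    subj_perm = rng.permutation(geno.index)
    snp_perm = rng.permutation(geno.columns)
    shuffled = GRSBuilder().fit(
        geno.loc[subj_perm, snp_perm], bmi.loc[subj_perm]
    ).retained_snps_
    assert sorted(base) == sorted(shuffled)


def test_null_cohort_screen_calibration_quick():
    """On fully null SNPs the stage-1 pass rate sits near alpha1 = 0.20."""
    specs = default_snp_panel(n_snps=95, n_causal=0)
    rates = []
    for seed in range(20):
        cohort, _, _ = simulate_cohort(
            CohortConfig(n_subjects=360, seed=300 + seed,
                         interaction_beta_female=0.0), specs=specs
        )
        scr = kw_screen(cohort[[s.snp_id for s in specs]], cohort["bmi"])
        rates.append(scr["passes"].mean())
    mean = np.mean(rates)
    se = np.sqrt(0.2 * 0.8 / (95 * 20))
    assert abs(mean - 0.20) < 4 * se


def test_builder_recovers_planted_snps_mostly():
    """Power property (reported, loosely asserted): most planted loci are
    retained on a default-size cohort."""
    hits = []
    for seed in (31, 32, 33):
        cohort, _, specs = simulate_cohort(CohortConfig(n_subjects=360, seed=seed))
        causal = {s.snp_id for s in specs if s.effect_model != "none"}
        b = GRSBuilder().fit(cohort[[s.snp_id for s in specs]], cohort["bmi"])
        hits.append(len(set(b.retained_snps_) & causal))
    assert np.mean(hits) >= 2  # genuine signal well above the null rate
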