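"""OLS, interaction regressions, predicted curves and WHO classification."""

import numpy as np
import pandas as pd
import pytest

from microgrs import bmi_classify, interaction_model, ols, predict_curve
from microgrs.simulate import CohortConfig, simulate_cohort


def _covariates(rng, n, sex=None):
    idx = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(
        {
            "age": rng.normal(45, 10, n),
            "mets": rng.normal(25, 10, n),
            "energy": rng.normal(2900, 500, n),
            "sex": sex if sex is not None
            else np.where(rng.random(n) < 0.5, "female", "male"),
        },
        index=idx,
    )


def test_ols_exact_line():
    x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    fit = ols([2.0, 4.0, 6.0, 8.0], x)
    assert fit["x"]["beta"] == pytest.approx(2.0)
    assert fit.r2 == pytest.approx(1.0)


def test_ols_matches_normal_equations(rng):
    X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    y = rng.normal(size=20)
    fit = ols(y, X)
    Xc = np.column_stack([np.ones(20), X.to_numpy()])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    np.testing.assert_allclose(fit.coef["beta"].to_numpy(), beta, atol=1e-10)
    resid = y - Xc @ beta
    s2 = resid @ resid / (20 - 4)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(Xc.T @ Xc)))
    np.testing.assert_allclose(fit.coef["se"].to_numpy(), se, atol=1e-10)
    ybar = y.mean()
    r2 = 1 - (resid @ resid) / ((y - ybar) @ (y - ybar))
    assert fit.r2 == pytest.approx(r2, abs=1e-12)
    assert fit.adj_r2 == pytest.approx(1 - (1 - r2) * 19 / (20 - 3 - 1), abs=1e-12)


def test_ols_rank_deficiency_names_columns(rng):
    X = pd.DataFrame({"a": rng.normal(size=15)})
    X["b"] = 2 * X["a"]
    with pytest.raises(ValueError, match="collinear"):
        ols(rng.normal(size=15), X)


def test_noise_column_does_not_raise_adjusted_r2(rng):
    """Adding pure noise to the design does not raise adjusted R^2 in
    expectation (the mean change is zero up to Monte-Carlo error, unlike
    plain R^2, which always increases)."""
    deltas, r2_deltas = [], []
    for _ in range(500):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 1.5 * X["x"].to_numpy() + rng.normal(size=40)
        base = ols(y, X)
        expanded = ols(y, X.assign(noise=rng.normal(size=40)))
        deltas.append(expanded.adj_r2 - base.adj_r2)
        r2_deltas.append(expanded.r2 - base.r2)
    mc_se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
    assert np.mean(deltas) <= 3 * mc_se
    assert min(r2_deltas) >= 0  # raw R^2, by contrast, never decreases


def test_interaction_null_beta_centers_on_zero():
    estimates, ses = [], []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        cov = _covariates(rng, 200, sex=np.array(["female"] * 200))
        grs = pd.Series(rng.integers(0, 11, 200), index=cov.index)
        ab = pd.Series(rng.lognormal(np.log(6), 0.7, 200), index=cov.index)
        bmi = 25 + 0.4 * grs + rng.normal(0, 3, 200)  # no interaction planted
        fit = interaction_model(pd.Series(bmi, index=cov.index), ab, grs, cov,
                                stratum="female")
        estimates.append(fit["abundance_x_grs"]["beta"])
        ses.append(fit["abundance_x_grs"]["se"])
    mean = np.mean(estimates)
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(mean) < 3 * mc_se


def test_sex_specific_interaction_pattern():
    """Female-only planted interaction: the women stratum recovers it, the
    men stratum centers near zero (reduced-size replicate check)."""
    women, men = [], []
    for seed in range(40):
        cohort, counts, _ = simulate_cohort(
            CohortConfig(n_subjects=360, seed=700 + seed)
        )
        focal = 100 * counts.loc["Prevotellaceae"] / counts.sum(axis=0)
        focal.index = cohort.index
        for stratum, sink in (("female", women), ("male", men)):
            fit = interaction_model(
                cohort["bmi"], focal, cohort["true_grs"],
                cohort[["age", "mets", "energy", "sex"]], stratum=stratum,
            )
            sink.append(fit["abundance_x_grs"]["beta"])
    w_mean = np.mean(women)
    w_se = np.std(women, ddof=1) / np.sqrt(len(women))
    m_mean = np.mean(men)
    m_se = np.std(men, ddof=1) / np.sqrt(len(men))
    assert abs(w_mean - 0.10) < 3 * w_se
    assert abs(m_mean) < 3 * m_se
    assert w_mean > m_mean  # the published sign pattern


def test_stratified_design_drops_sex_column(rng):
    cov = _covariates(rng, 60)
    grs = pd.Series(rng.integers(0, 11, 60), index=cov.index)
    ab = pd.Series(rng.lognormal(1.5, 0.5, 60), index=cov.index)
    bmi = pd.Series(rng.normal(29, 4, 60), index=cov.index)
    pooled = interaction_model(bmi, ab, grs, cov, stratum="all")
    stratified = interaction_model(bmi, ab, grs, cov, stratum="female")
    assert "sex_male" in pooled.coef.index
    assert "sex_male" not in stratified.coef.index
    with pytest.raises(ValueError):
        interaction_model(bmi, ab, grs, cov.assign(sex="female"), stratum="male")


def test_predict_curve_slope_gap_equals_interaction(rng):
    cov = _covariates(rng, 80, sex=np.array(["female"] * 80))
    grs = pd.Series(rng.integers(0, 11, 80), index=cov.index)
    ab = pd.Series(rng.lognormal(1.8, 0.6, 80), index=cov.index)
    bmi = pd.Series(
        24 + 0.3 * grs + 0.12 * ab * grs + rng.normal(0, 1, 80), index=cov.index
    )
    fit = interaction_model(bmi, ab, grs, cov, stratum="female")
    curve = predict_curve(fit, family_values=(5.0, 15.0), grs_range=range(0, 11))
    lo = curve[curve["abundance"] == 5.0].set_index("grs")["predicted_bmi"]
    hi = curve[curve["abundance"] == 15.0].set_index("grs")["predicted_bmi"]
    slope_lo = lo[10] - lo[9]
    slope_hi = hi[10] - hi[9]
    beta = fit["abundance_x_grs"]["beta"]
    assert slope_hi - slope_lo == pytest.approx(10 * beta, abs=1e-9)
    with pytest.raises(ValueError):
        predict_curve(fit, family_values=(150.0,))


def test_predict_curve_parallel_without_interaction(rng):
    n = 200
    cov = _covariates(rng, n, sex=np.array(["female"] * n))
    grs = pd.Series(rng.integers(0, 11, n), index=cov.index).astype(float)
    ab = pd.Series(rng.lognormal(1.5, 0.5, n), index=cov.index)
    bmi = pd.Series(25 + 0.5 * grs + rng.normal(0, 2, n), index=cov.index)
    fit = interaction_model(bmi, ab, grs, cov, stratum="female")
    # force a zero interaction and check exact parallelism of the curves
    fit.coef.loc["abundance_x_grs", "beta"] = 0.0
    curve = predict_curve(fit, family_values=(5.0, 15.0), grs_range=range(0, 5))
    lo = curve[curve["abundance"] == 5.0]["predicted_bmi"].to_numpy()
    hi = curve[curve["abundance"] == 15.0]["predicted_bmi"].to_numpy()
    np.testing.assert_allclose(np.diff(lo), np.diff(hi), atol=1e-12)


def test_ci_coverage_of_planted_coefficient(rng):
    """95% OLS confidence intervals cover the planted slope ~95% of the
    time."""
    from scipy import stats as sps

    covered = 0
    reps = 400
    tcrit = sps.t.ppf(0.975, 50 - 3)
    for _ in range(reps):
        X = pd.DataFrame({"x": rng.normal(size=50), "z": rng.normal(size=50)})
        y = 0.8 * X["x"].to_numpy() + rng.normal(size=50)
        fit = ols(y, X)
        lo = fit["x"]["beta"] - tcrit * fit["x"]["se"]
        hi = fit["x"]["beta"] + tcrit * fit["x"]["se"]
        covered += lo <= 0.8 <= hi
    rate = covered / reps
    assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps)


def test_bmi_classification_boundaries():
    assert bmi_classify(24.0) == "normalweight"
    assert bmi_classify(27.0) == "overweight"
    assert bmi_classify(27.0, binary=True) == "overweight+obese"
    assert bmi_classify(31.7) == "obese"
    eps = np.nextafter(25.0, 0.0)
    assert bmi_classify(eps) == "normalweight"
    assert bmi_classify(25.0) == "overweight"
    assert bmi_classify(30.0) == "obese"
    with pytest.raises(ValueError):
        bmi_classify(0.0)
    s = pd.Series([22.0, 26.0, 33.0])
    assert bmi_classify(s).tolist() == ["normalweight", "overweight", "obese"]
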