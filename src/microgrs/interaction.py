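"""BMI ~ family abundance x GRS interaction regressions.

Ordinary least squares with the covariate set used throughout the package
(age, physical activity in METs, energy intake, plus sex in pooled fits),
sex stratification, predicted-BMI curves at fixed abundance values, and
WHO BMI classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "ModelFit",
    "ols",
    "interaction_model",
    "predict_curve",
    "bmi_classify",
    "InteractionModel",
]


@dataclass
class ModelFit:
    """OLS fit summary: per-coefficient beta/SE/t/p plus model-level stats."""

    coef: pd.DataFrame  # index = term; columns beta, se, t, pvalue
    r2: float
    adj_r2: float
    f_pvalue: float
    n: int
    design_means: pd.Series = field(default=None, repr=False)
    _results: object = field(default=None, repr=False)

    def __getitem__(self, term: str) -> pd.Series:
        return self.coef.loc[term]


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for col in design.columns:
            rest = design.drop(columns=[col]).to_numpy(float)
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols(y, design: pd.DataFrame) -> ModelFit:
    """Least squares of y on a named design matrix.

    A constant column is added unless one is present.  Standard errors use
    the unbiased residual variance; adjusted R^2 = 1-(1-R^2)(n-1)/(n-p-1).
    """
    design = pd.DataFrame(design).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=design.index)
    if not (design.std(ddof=0) == 0).any():
        design = design.copy()
        design.insert(0, "const", 1.0)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need n > number of parameters ({n} <= {p})")
    _check_rank(design)
    res = sm.OLS(y, design).fit()
    coef = pd.DataFrame(
        {"beta": res.params, "se": res.bse, "t": res.tvalues, "pvalue": res.pvalues}
    )
    return ModelFit(
        coef=coef,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_pvalue=float(res.f_pvalue),
        n=int(res.nobs),
        design_means=design.mean(),
        _results=res,
    )


def _build_design(abundance, grs, covariates, include_sex):
    design = pd.DataFrame(
        {
            "abundance": np.asarray(abundance, dtype=float),
            "grs": np.asarray(grs, dtype=float),
            "abundance_x_grs": np.asarray(abundance, dtype=float)
            * np.asarray(grs, dtype=float),
            "age": covariates["age"].to_numpy(float),
            "mets": covariates["mets"].to_numpy(float),
            "energy": covariates["energy"].to_numpy(float),
        },
        index=covariates.index,
    )
    if include_sex:
        design["sex_male"] = (covariates["sex"].to_numpy() == "male").astype(float)
    return design


def interaction_model(
    bmi: pd.Series,
    family_relabund: pd.Series,
    grs: pd.Series,
    covariates: pd.DataFrame,
    stratum: str = "all",
) -> ModelFit:
    """Fit BMI ~ abundance + GRS + abundance x GRS + age + METs + energy,
    with sex as an additional covariate in the pooled ("all") fit only.

    ``stratum`` is "all" or a sex label ("female"/"male"); stratified fits
    drop the sex column and the subjects outside the stratum.
    """
    bmi = pd.Series(bmi).astype(float)
    idx = bmi.index
    family_relabund = pd.Series(family_relabund).reindex(idx)
    grs = pd.Series(grs).reindex(idx)
    covariates = pd.DataFrame(covariates).reindex(idx)
    keep = (
        bmi.notna() & family_relabund.notna() & grs.notna()
        & covariates[["age", "mets", "energy"]].notna().all(axis=1)
    )
    if stratum != "all":
        keep &= covariates["sex"] == stratum
    if not keep.any():
        raise ValueError(f"stratum {stratum!r} is empty")
    design = _build_design(
        family_relabund[keep], grs[keep], covariates.loc[keep], include_sex=stratum == "all"
    )
    return ols(bmi[keep], design)


def predict_curve(
    fit: ModelFit,
    family_values=(5.0, 15.0),
    grs_range=None,
) -> pd.DataFrame:
    """Predicted BMI over a GRS grid at fixed abundance values, with the
    remaining covariates held at their fit-sample means.

    The slope difference between two curves at abundances a1 < a2 equals
    (a2 - a1) x the interaction coefficient per GRS unit.
    """
    required = {"abundance", "grs", "abundance_x_grs"}
    if not required.issubset(fit.coef.index):
        raise ValueError("fit does not contain abundance, grs and interaction terms")
    for v in family_values:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"abundance value {v} outside the percent scale [0, 100]")
    if grs_range is None:
        mean = fit.design_means["grs"]
        grs_range = np.arange(0, int(np.ceil(mean * 2)) + 1)
    rows = []
    for a in family_values:
        for g in grs_range:
            x = fit.design_means.copy()
            x["abundance"] = a
            x["grs"] = float(g)
            x["abundance_x_grs"] = a * float(g)
            pred = float(np.dot(x.to_numpy(), fit.coef["beta"].to_numpy()))
            rows.append({"abundance": a, "grs": float(g), "predicted_bmi": pred})
    return pd.DataFrame(rows)


def bmi_classify(bmi, binary: bool = False):
    """WHO BMI class: normalweight (< 25), overweight ([25, 30)), obese
    (>= 30); with ``binary=True`` overweight and obese merge into
    "overweight+obese"."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("BMI must be positive")
    labels = np.where(arr < 25.0, "normalweight", np.where(arr < 30.0, "overweight", "obese"))
    if binary:
        labels = np.where(labels == "normalweight", "normalweight", "overweight+obese")
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(labels)
    if isinstance(bmi, pd.Series):
        return pd.Series(labels, index=bmi.index, name="bmi_class")
    return labels


class InteractionModel(BaseEstimator):
    """Sex-stratifiable abundance x GRS interaction regression.

    ``fit(X, y)`` expects ``X`` with columns abundance, grs, age, mets,
    energy, sex and ``y`` the BMI vector; the fitted :class:`ModelFit` is
    stored in ``fit_`` and predictions use :func:`predict_curve`.
    """

    def __init__(self, stratum: str = "all"):
        self.stratum = stratum

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        self.fit_ = interaction_model(
            y, X["abundance"], X["grs"],
            X[["age", "mets", "energy", "sex"]] if "sex" in X else X,
            stratum=self.stratum,
        )
        return self

    def predict_curve(self, family_values=(5.0, 15.0), grs_range=None) -> pd.DataFrame:
        if not hasattr(self, "fit_"):
            raise ValueError("InteractionModel is not fitted")
        return predict_curve(self.fit_, family_values, grs_range)
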