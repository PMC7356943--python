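"""Data-driven genetic risk score (GRS) construction.

The score is built in three stages on a training cohort:

1. *Screen* — a Kruskal-Wallis test of BMI across the three genotype
   categories of every SNP; SNPs with p below a lenient threshold
   (default 0.20) continue.
2. *Code* — pairwise Mann-Whitney post-hoc tests order the genotype groups
   by median BMI and merge adjacent groups with similar effects into a
   single category, yielding a binary risk / non-risk partition per SNP
   where the risk side has the higher median BMI.
3. *Confirm and filter* — a two-group Mann-Whitney test on the binary
   coding (retain p < 0.10), a low-count filter (each category must hold at
   least 10% of genotyped subjects) and a collinearity filter on the coded
   0/1 indicators.

The GRS of a subject is the number of retained loci at which the subject's
genotype falls in the risk category — a per-locus indicator sum, not an
allele count, so the maximum equals the number of retained SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import TestResult, hwe_test, kruskal_wallis, mann_whitney

__all__ = [
    "RiskCoding",
    "SelectionReport",
    "GRSBuilder",
    "hwe_test",
    "kw_screen",
    "derive_risk_coding",
    "confirm_and_filter",
    "compute_grs",
    "split_by_mean",
]

_MISSING = {".", "", "NA", "nan", "None"}


def _observed(genotypes: pd.Series, bmi: pd.Series):
    """Aligned (genotype, bmi) over subjects with a non-missing genotype."""
    g = genotypes.astype("string")
    mask = g.notna() & ~g.isin(_MISSING)
    return g[mask], bmi.loc[g[mask].index]


@dataclass
class RiskCoding:
    """Binary risk / non-risk partition of one SNP's genotype categories."""

    snp_id: str
    risk_genotypes: frozenset = frozenset()
    nonrisk_genotypes: frozenset = frozenset()
    stage1_p: float | None = None
    stage3_p: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None  # low-count | collinearity | nonsignificant

    def __post_init__(self):
        self.risk_genotypes = frozenset(self.risk_genotypes)
        self.nonrisk_genotypes = frozenset(self.nonrisk_genotypes)
        if not self.excluded:
            if not self.risk_genotypes or not self.nonrisk_genotypes:
                raise ValueError(f"{self.snp_id}: both coding categories must be non-empty")
            if self.risk_genotypes & self.nonrisk_genotypes:
                raise ValueError(f"{self.snp_id}: risk and non-risk categories overlap")

    @property
    def genotypes(self) -> frozenset:
        return self.risk_genotypes | self.nonrisk_genotypes

    def indicator(self, genotypes: pd.Series) -> pd.Series:
        """0/1 risk indicator; raises on genotype categories never coded."""
        g = genotypes.astype("string")
        known = self.genotypes
        observed = g.dropna()[~g.dropna().isin(_MISSING)]
        unknown = observed[~observed.isin(known)]
        if len(unknown):
            subj = unknown.index[0]
            raise ValueError(
                f"unknown genotype {unknown.iloc[0]!r} for SNP {self.snp_id} "
                f"at subject {subj}"
            )
        out = pd.Series(np.nan, index=genotypes.index, dtype=float)
        out[observed.index] = observed.isin(self.risk_genotypes).astype(float)
        return out


@dataclass
class SelectionReport:
    """Outcome of the three-stage selection: all codings plus retained set."""

    codings: list[RiskCoding]
    retained: list[str] = field(default_factory=list)

    def coding(self, snp_id: str) -> RiskCoding:
        for c in self.codings:
            if c.snp_id == snp_id:
                return c
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.codings:
            rows.append(
                {
                    "snp": c.snp_id,
                    "non_risk_genotype": "+".join(sorted(c.nonrisk_genotypes)),
                    "risk_genotype": "+".join(sorted(c.risk_genotypes)),
                    "stage1_p": c.stage1_p,
                    "stage3_p": c.stage3_p,
                    "retained": c.snp_id in self.retained,
                    "exclusion_reason": c.exclusion_reason or "",
                }
            )
        return pd.DataFrame(rows)


def kw_screen(
    genotypes: pd.DataFrame,
    bmi: pd.Series,
    alpha1: float = 0.20,
    method: str = "auto",
) -> pd.DataFrame:
    """Stage 1: per-SNP Kruskal-Wallis p of BMI across genotype groups.

    SNPs without >= 2 genotype groups of >= 2 subjects are flagged
    untestable rather than raising.
    """
    rows = []
    for snp in genotypes.columns:
        g, y = _observed(genotypes[snp], bmi)
        groups = [y[g == cat].to_numpy() for cat in sorted(g.unique())]
        groups = [grp for grp in groups if len(grp) > 0]
        if len(groups) < 2 or sum(len(grp) >= 2 for grp in groups) < 2:
            rows.append({"snp": snp, "pvalue": np.nan, "passes": False, "testable": False})
            continue
        res = kruskal_wallis(groups, method=method)
        rows.append(
            {"snp": snp, "pvalue": res.pvalue, "passes": res.pvalue < alpha1, "testable": True}
        )
    return pd.DataFrame(rows).set_index("snp")


def derive_risk_coding(
    genotypes: pd.Series,
    bmi: pd.Series,
    merge_alpha: float = 0.05,
    stage1_p: float | None = None,
    mw_method: str = "auto",
    snp_id: str | None = None,
) -> RiskCoding:
    """Stage 2: order genotype groups by median BMI, merge similar adjacent
    groups (pairwise Mann-Whitney p >= merge_alpha), label the higher-median
    side risk.

    If all observed groups merge into one, the SNP is excluded (no valid
    split).  If three distinct groups remain, the binary split with the
    stronger Mann-Whitney separation is chosen.
    """
    snp_id = snp_id or (genotypes.name or "snp")
    g, y = _observed(genotypes, bmi)
    cats = sorted(g.unique(), key=lambda c: (float(y[g == c].median()), c))
    values = {c: y[g == c].to_numpy() for c in cats}
    if len(cats) < 2:
        return RiskCoding(snp_id, excluded=True, exclusion_reason="nonsignificant",
                          stage1_p=stage1_p)

    def mw_p(a, b):
        return mann_whitney(values[a], values[b], method=mw_method).pvalue

    if len(cats) == 2:
        if mw_p(cats[0], cats[1]) >= merge_alpha:
            return RiskCoding(snp_id, excluded=True, exclusion_reason="nonsignificant",
                              stage1_p=stage1_p)
        low, high = [cats[0]], [cats[1]]
    else:
        p01 = mw_p(cats[0], cats[1])
        p12 = mw_p(cats[1], cats[2])
        merge01 = p01 >= merge_alpha
        merge12 = p12 >= merge_alpha
        if merge01 and merge12:
            return RiskCoding(snp_id, excluded=True, exclusion_reason="nonsignificant",
                              stage1_p=stage1_p)
        if merge01:
            low, high = [cats[0], cats[1]], [cats[2]]
        elif merge12:
            low, high = [cats[0]], [cats[1], cats[2]]
        else:
            # three separable groups: pick the split with the stronger
            # binary Mann-Whitney separation
            lo_split = mann_whitney(
                values[cats[0]], np.concatenate([values[c] for c in cats[1:]]),
                method=mw_method,
            ).pvalue
            hi_split = mann_whitney(
                np.concatenate([values[c] for c in cats[:2]]), values[cats[2]],
                method=mw_method,
            ).pvalue
            if lo_split <= hi_split:
                low, high = [cats[0]], [cats[1], cats[2]]
            else:
                low, high = [cats[0], cats[1]], [cats[2]]
    return RiskCoding(
        snp_id,
        risk_genotypes=frozenset(high),
        nonrisk_genotypes=frozenset(low),
        stage1_p=stage1_p,
    )


def confirm_and_filter(
    codings: list[RiskCoding],
    genotypes: pd.DataFrame,
    bmi: pd.Series,
    alpha2: float = 0.10,
    min_frac: float = 0.10,
    collinearity_r: float = 0.8,
    mw_method: str = "auto",
) -> SelectionReport:
    """Stage 3: confirm each binary coding with a two-group Mann-Whitney
    test (retain p < alpha2), drop codings with a category holding fewer
    than ``min_frac`` of genotyped subjects, then prune collinear codings
    (pairwise |Pearson r| of the 0/1 indicators > ``collinearity_r``,
    dropping the larger stage-3 p)."""
    candidates = [c for c in codings if not c.excluded]
    if not candidates:
        warnings.warn("no candidate codings to confirm", UserWarning, stacklevel=2)
        return SelectionReport(codings=list(codings))

    survivors: list[RiskCoding] = []
    indicators: dict[str, pd.Series] = {}
    for c in candidates:
        ind = c.indicator(genotypes[c.snp_id]).dropna()
        y = bmi.loc[ind.index]
        risk = y[ind == 1].to_numpy()
        nonrisk = y[ind == 0].to_numpy()
        if len(risk) == 0 or len(nonrisk) == 0:
            c.excluded, c.exclusion_reason = True, "low-count"
            continue
        c.stage3_p = mann_whitney(risk, nonrisk, method=mw_method).pvalue
        frac = min(len(risk), len(nonrisk)) / len(ind)
        if frac < min_frac:
            c.excluded, c.exclusion_reason = True, "low-count"
        elif not c.stage3_p < alpha2:
            c.excluded, c.exclusion_reason = True, "nonsignificant"
        else:
            survivors.append(c)
            indicators[c.snp_id] = ind

    # collinearity pruning: repeatedly drop the weaker member of the most
    # correlated offending pair
    while True:
        worst = None
        for i, a in enumerate(survivors):
            for b in survivors[i + 1 :]:
                ia, ib = indicators[a.snp_id].align(indicators[b.snp_id], join="inner")
                if len(ia) < 3 or ia.std() == 0 or ib.std() == 0:
                    continue
                r = abs(float(np.corrcoef(ia, ib)[0, 1]))
                if r > collinearity_r and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        drop = a if (a.stage3_p or 0) >= (b.stage3_p or 0) else b
        drop.excluded, drop.exclusion_reason = True, "collinearity"
        survivors.remove(drop)

    return SelectionReport(codings=list(codings), retained=sorted(c.snp_id for c in survivors))


def compute_grs(
    report: SelectionReport | list[RiskCoding],
    genotypes: pd.DataFrame,
    return_excluded: bool = False,
):
    """GRS per subject: count of retained loci with the genotype in the
    risk category.  Subjects missing a genotype at any retained locus are
    excluded from the score (optionally returned as a list)."""
    if isinstance(report, SelectionReport):
        codings = [report.coding(s) for s in report.retained]
    else:
        codings = [c for c in report if not c.excluded]
    if not codings:
        raise ValueError("no retained SNPs: cannot compute a GRS")
    parts = []
    for c in codings:
        if c.snp_id not in genotypes.columns:
            raise KeyError(f"retained SNP {c.snp_id} missing from genotype matrix")
        parts.append(c.indicator(genotypes[c.snp_id]))
    mat = pd.concat(parts, axis=1)
    complete = mat.notna().all(axis=1)
    grs = mat[complete].sum(axis=1).astype(int).rename("grs")
    excluded = list(genotypes.index[~complete])
    if return_excluded:
        return grs, excluded
    return grs


def split_by_mean(grs: pd.Series) -> pd.Series:
    """High/low GRS groups split at the population mean (ties go high)."""
    if len(grs) < 2:
        raise ValueError("split_by_mean requires >= 2 subjects")
    mean = float(np.mean(grs))
    labels = pd.Series(np.where(np.asarray(grs, dtype=float) >= mean, "high", "low"),
                       index=grs.index, name="grs_group")
    if labels.nunique() == 1:
        warnings.warn("constant GRS: mean split yields a single group",
                      UserWarning, stacklevel=2)
    return labels


class GRSBuilder(BaseEstimator, TransformerMixin):
    """Learn a data-driven genetic risk score from genotypes and BMI.

    Parameters follow the three-stage construction: ``alpha1`` for the
    Kruskal-Wallis screen, ``merge_alpha`` for post-hoc genotype merging,
    ``alpha2``/``min_frac``/``collinearity_r`` for the confirmation filter.

    Fitted attributes
    -----------------
    screen_ : DataFrame of stage-1 p-values per SNP
    codings_ : list of RiskCoding for every screened SNP
    report_ : SelectionReport with the retained set
    retained_snps_ : list of retained SNP ids
    """

    def __init__(
        self,
        alpha1: float = 0.20,
        merge_alpha: float = 0.05,
        alpha2: float = 0.10,
        min_frac: float = 0.10,
        collinearity_r: float = 0.8,
        test_method: str = "auto",
    ):
        self.alpha1 = alpha1
        self.merge_alpha = merge_alpha
        self.alpha2 = alpha2
        self.min_frac = min_frac
        self.collinearity_r = collinearity_r
        self.test_method = test_method

    def fit(self, X: pd.DataFrame, y):
        genotypes = pd.DataFrame(X)
        bmi = pd.Series(np.asarray(y, dtype=float), index=genotypes.index)
        self.screen_ = kw_screen(genotypes, bmi, alpha1=self.alpha1, method=self.test_method)
        codings = []
        for snp in genotypes.columns:
            row = self.screen_.loc[snp]
            if not row["passes"]:
                codings.append(
                    RiskCoding(snp, stage1_p=row["pvalue"], excluded=True,
                               exclusion_reason="nonsignificant")
                )
                continue
            codings.append(
                derive_risk_coding(
                    genotypes[snp], bmi, merge_alpha=self.merge_alpha,
                    stage1_p=row["pvalue"], mw_method=self.test_method, snp_id=snp,
                )
            )
        self.codings_ = codings
        self.report_ = confirm_and_filter(
            codings, genotypes, bmi,
            alpha2=self.alpha2, min_frac=self.min_frac,
            collinearity_r=self.collinearity_r, mw_method=self.test_method,
        )
        self.retained_snps_ = list(self.report_.retained)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        """Integer GRS per subject (subjects with missing retained
        genotypes are dropped)."""
        if not hasattr(self, "report_"):
            raise ValueError("GRSBuilder is not fitted")
        return compute_grs(self.report_, pd.DataFrame(X))
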