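"""Two-group differential-abundance discovery at the family level.

Three complementary routes, mirroring common amplicon practice:

* a Kruskal-Wallis screen plus a bootstrapped one-dimensional linear
  discriminant effect size (LEfSe-style scores on a log10 scale),
* a zero-inflated Gaussian (ZIG) regression on CSS-normalized log2 counts
  with Benjamini-Hochberg q-values (metagenomeSeq-style),
* random-forest feature importance by out-of-bag permutation (mean
  decrease in accuracy, MDA) with held-out ROC AUC validation.

Feature matrices are families x samples; ``labels`` is a per-sample
two-class vector aligned with the columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from ._stats import bh_adjust, kruskal_wallis, roc_auc
from .prep import css_normalize

__all__ = [
    "kw_class_test",
    "lda_effect_size",
    "zig_fit",
    "rf_rank",
    "bh_adjust",
    "roc_auc",
    "ImportanceRanking",
    "LDAEffectSize",
    "ZIGDifferentialAbundance",
    "RandomForestRanker",
]


def _two_classes(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly two classes, got {list(classes)}")
    return labels, classes


def kw_class_test(features: pd.DataFrame, labels, method: str = "auto") -> pd.Series:
    """Per-family tie-corrected Kruskal-Wallis p between two classes."""
    features = pd.DataFrame(features)
    labels, classes = _two_classes(labels)
    pvals = {}
    for fam, row in features.iterrows():
        groups = [row.to_numpy(float)[labels == c] for c in classes]
        pvals[fam] = kruskal_wallis(groups, method=method).pvalue
    return pd.Series(pvals, name="kw_p")


def lda_effect_size(
    features: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    lda_min: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    kw_method: str = "auto",
) -> pd.DataFrame:
    """LEfSe-style effect sizes.

    Features are rescaled to sum 1e6 per sample.  Families passing the
    Kruskal-Wallis screen (p < alpha) get a bootstrapped one-dimensional
    Fisher discriminant effect (class-mean difference along the
    regularized discriminant direction, averaged over ``n_boot`` rounds);
    LDA score = log10(10 + |effect| / 2).  ``passes_threshold`` requires
    both the screen and score >= ``lda_min``.
    """
    features = pd.DataFrame(features).astype(float)
    labels, classes = _two_classes(labels)
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 samples")
    rng = np.random.default_rng(seed)

    colsum = features.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("samples with zero total abundance are not allowed")
    scaled = features * (1e6 / colsum)

    kw_p = kw_class_test(scaled, labels, method=kw_method)
    cls0 = np.flatnonzero(labels == classes[0])
    cls1 = np.flatnonzero(labels == classes[1])
    # canonical resampling order (by sample membership, not label name)
    # keeps the scores invariant under relabeling the two classes
    idx0, idx1 = (cls1, cls0) if cls1[0] < cls0[0] else (cls0, cls1)

    rows = []
    for fam, row in scaled.iterrows():
        x = row.to_numpy(float)
        enriched = classes[1] if x[cls1].mean() >= x[cls0].mean() else classes[0]
        p = float(kw_p[fam])
        if p < alpha:
            effects = np.empty(n_boot)
            for b in range(n_boot):
                b0 = rng.choice(idx0, size=idx0.size, replace=True)
                b1 = rng.choice(idx1, size=idx1.size, replace=True)
                d = x[b1].mean() - x[b0].mean()
                v0, v1 = x[b0].var(), x[b1].var()
                pooled = (idx0.size * v0 + idx1.size * v1) / (idx0.size + idx1.size)
                # regularized discriminant direction fixes the sign;
                # the projected class-mean gap is |d| along it
                w = d / (pooled + 1e-6 * max(pooled, 1.0))
                effects[b] = np.sign(w) * abs(d) if w != 0 else 0.0
            eff = float(np.mean(effects))
            score = float(np.log10(10.0 + abs(eff) / 2.0))
        else:
            eff, score = np.nan, np.nan
        rows.append(
            {
                "family": fam,
                "kw_p": p,
                "enriched": enriched,
                "effect": eff,
                "lda_score": score,
                "passes_threshold": bool(p < alpha and score >= lda_min)
                if not np.isnan(score)
                else False,
            }
        )
    return pd.DataFrame(rows).set_index("family")


def _fit_logistic(r: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Fractional-response logistic fit for the zero-model (E-step
    responsibilities as the response); falls back to an intercept-only
    model when the GLM fails to converge."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(r, design, family=sm.families.Binomial()).fit(maxiter=50)
            return np.asarray(res.params)
        except Exception:
            mean = float(np.clip(r.mean(), 1e-10, 1 - 1e-10))
            return np.array([np.log(mean / (1 - mean))] + [0.0] * (design.shape[1] - 1))


def _zig_single(y, zero, group, log_lib, max_iter, tol):
    """EM fit of the zero-inflated Gaussian for one family.

    Returns (beta_group, se, z, p, loglik_trace, converged).
    """
    n = y.size
    x_gauss = np.column_stack([np.ones(n), group])
    x_zero = np.column_stack([np.ones(n), log_lib])

    r = np.where(zero, 0.5, 0.0)  # P(spike | y)
    has_zeros = bool(zero.any())
    if not has_zeros:
        r[:] = 0.0
    theta = np.array([0.0, 0.0])
    trace = []
    converged = False
    beta = se = sigma2 = None
    for _ in range(max_iter):
        # M-step
        w = 1.0 - r
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x_gauss * sw[:, None], y * sw, rcond=None)
        resid = y - x_gauss @ beta
        sigma2 = max(float((w * resid**2).sum() / max(w.sum(), 1e-12)), 1e-12)
        if has_zeros:
            theta = _fit_logistic(r, x_zero)
        pi = 1.0 / (1.0 + np.exp(-(x_zero @ theta))) if has_zeros else np.zeros(n)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)

        dens = sps.norm.pdf(y, loc=x_gauss @ beta, scale=np.sqrt(sigma2))
        ll = float(
            np.sum(np.log(pi[zero] + (1 - pi[zero]) * dens[zero]))
            + np.sum(np.log((1 - pi[~zero]) * np.maximum(dens[~zero], 1e-300)))
        ) if has_zeros else float(np.sum(np.log(np.maximum(dens, 1e-300))))
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # E-step
        if has_zeros:
            r = np.zeros(n)
            r[zero] = pi[zero] / (pi[zero] + (1 - pi[zero]) * dens[zero])
        if not has_zeros:
            converged = True
            break

    w = 1.0 - r
    xtwx = x_gauss.T @ (x_gauss * w[:, None])
    cov = sigma2 * np.linalg.inv(xtwx)
    se = float(np.sqrt(cov[1, 1]))
    z = float(beta[1] / se) if se > 0 else np.nan
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return float(beta[1]), se, z, p, trace, converged


@dataclass
class ZIGFamilyFit:
    loglik_trace: list
    converged: bool


def zig_fit(
    m: pd.DataFrame,
    labels,
    css_quantile="auto",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Zero-inflated Gaussian differential abundance on CSS-normalized
    log2 counts.

    Per family, an EM fit of a two-component mixture: a point mass at zero
    whose weight follows a logistic model on log library size, and a
    Gaussian on log2(CSS count + 1) with mean = intercept + group effect.
    Reports the group coefficient (log2 scale), its z-test and BH-FDR
    q-values across families.  All-zero families are skipped with a flag.
    """
    m = pd.DataFrame(m)
    labels, classes = _two_classes(labels)
    if min((labels == c).sum() for c in classes) < 3:
        raise ValueError("each class needs >= 3 samples")
    libsize = m.sum(axis=0).to_numpy(float)
    if (libsize == 0).any():
        raise ValueError("samples with zero library size are not allowed")
    log_lib = np.log(libsize)
    group = (labels == classes[1]).astype(float)

    scaled, _ = css_normalize(m, quantile=css_quantile)
    y_all = np.log2(scaled.to_numpy(float) + 1.0)
    zero_all = m.to_numpy(float) == 0

    rows = []
    traces = {}
    for i, fam in enumerate(m.index):
        zero = zero_all[i]
        if zero.all():
            rows.append(
                {"family": fam, "coef": np.nan, "se": np.nan, "z": np.nan,
                 "pvalue": np.nan, "skipped": True, "converged": False}
            )
            continue
        coef, se, z, p, trace, conv = _zig_single(
            y_all[i], zero, group, log_lib, max_iter, tol
        )
        if not conv:
            warnings.warn(f"ZIG EM did not converge for family {fam!r}; "
                          "last iterate reported", UserWarning, stacklevel=2)
        traces[fam] = ZIGFamilyFit(trace, conv)
        rows.append(
            {"family": fam, "coef": coef, "se": se, "z": z, "pvalue": p,
             "skipped": False, "converged": conv}
        )
    out = pd.DataFrame(rows).set_index("family")
    tested = out.index[~out["skipped"]]
    out["qvalue"] = np.nan
    if len(tested):
        out.loc[tested, "qvalue"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    out.attrs["em_traces"] = traces
    out.attrs["classes"] = list(classes)
    return out


@dataclass
class ImportanceRanking:
    """Mean-decrease-accuracy ranking across repeated random forests."""

    table: pd.DataFrame  # family -> mean_mda, rank
    per_repeat: pd.DataFrame  # family x repeat MDA values
    aucs: list  # held-out ROC AUC per repeat


def _oob_mda(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Breiman-style MDA: per tree, permute each feature among that tree's
    out-of-bag samples and average the accuracy decrease.  Features a tree
    never splits on contribute an exact zero for that tree."""
    n, p = X.shape
    decreases = np.zeros(p)
    counts = np.zeros(p)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        if oob.sum() < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = float(np.mean(tree.predict(Xo) == yo))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        counts += 1
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            decreases[f] += base - float(np.mean(tree.predict(Xp) == yo))
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, decreases / np.maximum(counts, 1), 0.0)


def rf_rank(
    features: pd.DataFrame,
    labels,
    n_trees: int = 500,
    n_repeats: int = 10,
    train_frac: float = 0.70,
    seed: int = 0,
    max_split_attempts: int = 10,
) -> ImportanceRanking:
    """Random-forest importance ranking with out-of-bag permutation MDA.

    Per repeat: a stratified ``train_frac`` split, a forest of ``n_trees``
    on the training part, MDA by out-of-bag permutation, and ROC AUC of
    the class-1 probability on the held-out part.  Mean MDA across repeats
    is ranked descending (rank 1 = most important).
    """
    features = pd.DataFrame(features).astype(float)
    labels, classes = _two_classes(labels)
    if min((labels == c).sum() for c in classes) < 10:
        raise ValueError("each class needs >= 10 samples")
    X = features.to_numpy(float).T  # samples x families
    y = (labels == classes[1]).astype(int)

    rng = np.random.default_rng(seed)
    mda = {}
    aucs = []
    for rep in range(n_repeats):
        for attempt in range(max_split_attempts):
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=train_frac,
                random_state=int(rng.integers(2**31)),
            )
            train, test = next(splitter.split(X, y))
            if min(np.bincount(y[train], minlength=2)) >= 2:
                break
            warnings.warn("degenerate split resampled", UserWarning, stacklevel=2)
        forest = RandomForestClassifier(
            n_estimators=n_trees, bootstrap=True,
            random_state=int(rng.integers(2**31)), n_jobs=1,
        ).fit(X[train], y[train])
        mda[rep] = _oob_mda(forest, X[train], y[train], rng)
        aucs.append(roc_auc(forest.predict_proba(X[test])[:, 1], y[test]))

    per_repeat = pd.DataFrame(mda, index=features.index)
    mean_mda = per_repeat.mean(axis=1)
    order = mean_mda.sort_values(ascending=False, kind="mergesort")
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table = pd.DataFrame({"mean_mda": mean_mda, "rank": rank.reindex(mean_mda.index)})
    return ImportanceRanking(table=table, per_repeat=per_repeat, aucs=aucs)


class LDAEffectSize(BaseEstimator):
    """Estimator wrapper for :func:`lda_effect_size`; results in ``results_``."""

    def __init__(self, alpha: float = 0.05, lda_min: float = 2.0,
                 n_boot: int = 30, seed: int = 0, kw_method: str = "auto"):
        self.alpha = alpha
        self.lda_min = lda_min
        self.n_boot = n_boot
        self.seed = seed
        self.kw_method = kw_method

    def fit(self, X, y):
        self.results_ = lda_effect_size(
            X, y, alpha=self.alpha, lda_min=self.lda_min,
            n_boot=self.n_boot, seed=self.seed, kw_method=self.kw_method,
        )
        return self


class ZIGDifferentialAbundance(BaseEstimator):
    """Estimator wrapper for :func:`zig_fit`; results in ``results_``."""

    def __init__(self, css_quantile="auto", max_iter: int = 100, tol: float = 1e-8):
        self.css_quantile = css_quantile
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        self.results_ = zig_fit(X, y, css_quantile=self.css_quantile,
                                max_iter=self.max_iter, tol=self.tol)
        return self


class RandomForestRanker(BaseEstimator):
    """Estimator wrapper for :func:`rf_rank`; ranking in ``ranking_``."""

    def __init__(self, n_trees: int = 500, n_repeats: int = 10,
                 train_frac: float = 0.70, seed: int = 0):
        self.n_trees = n_trees
        self.n_repeats = n_repeats
        self.train_frac = train_frac
        self.seed = seed

    def fit(self, X, y):
        self.ranking_ = rf_rank(X, y, n_trees=self.n_trees,
                                n_repeats=self.n_repeats,
                                train_frac=self.train_frac, seed=self.seed)
        return self
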