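"""Family-level count-matrix preparation and diversity statistics.

Matrices follow the amplicon convention: rows are taxa (families), columns
are samples, entries are non-negative counts, and a sample's library size
is its column sum.  Shannon diversity is reported in nats; Chao1 uses the
bias-corrected estimator so samples without doubletons are defined.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureFilter",
    "CSSNormalizer",
    "filter_features",
    "relative_abundance",
    "css_normalize",
    "shannon",
    "chao1",
    "bray_curtis",
    "diversity_table",
    "diversity_association",
]


def _validate_counts(m: pd.DataFrame) -> pd.DataFrame:
    m = pd.DataFrame(m)
    if (m.to_numpy() < 0).any():
        raise ValueError("count matrix must be non-negative")
    return m


def filter_features(
    m: pd.DataFrame, min_prevalence: float = 0.10, min_total: int = 10
) -> pd.DataFrame:
    """Keep families present (count > 0) in >= ``min_prevalence`` of samples
    and with total count >= ``min_total``."""
    m = _validate_counts(m)
    prevalence = (m > 0).mean(axis=1)
    keep = (prevalence >= min_prevalence) & (m.sum(axis=1) >= min_total)
    removed = m.index[~keep]
    if len(removed):
        logger.info("filter_features removed %d families: %s",
                    len(removed), ", ".join(map(str, removed[:10])))
    if not keep.any():
        raise ValueError(
            f"filtering with min_prevalence={min_prevalence}, min_total={min_total} "
            "removed every family"
        )
    return m.loc[keep]


def relative_abundance(m: pd.DataFrame) -> pd.DataFrame:
    """Percent relative abundance: each sample (column) sums to 100."""
    m = _validate_counts(m)
    libsize = m.sum(axis=0)
    if (libsize == 0).any():
        bad = libsize.index[libsize == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    return 100.0 * m / libsize


def _css_quantile_auto(m: pd.DataFrame, grid_step: float = 0.05) -> float:
    """Stability scan: the first grid quantile at which the median (across
    samples) of the per-sample nonzero-count quantile changes by more than
    10% relative to the previous grid point; 0.5 if the scan never
    triggers."""
    grid = np.arange(grid_step, 1.0 + 1e-9, grid_step)
    med = []
    for q in grid:
        vals = [
            np.quantile(col[col > 0], q) for _, col in m.items() if (col > 0).any()
        ]
        med.append(float(np.median(vals)))
    for i in range(1, len(grid)):
        if med[i - 1] > 0 and abs(med[i] - med[i - 1]) / med[i - 1] > 0.1:
            return float(grid[i])
    return 0.5


def css_normalize(m: pd.DataFrame, quantile="auto", log2: bool = False):
    """Cumulative sum scaling normalization.

    Each sample is divided by the sum of its counts up to the chosen
    quantile of its nonzero-count distribution and rescaled by the median
    of those factors, so the output stays on a count-like scale.
    ``quantile=1.0`` reduces to total-sum scaling.  Returns
    (normalized matrix, per-sample scale factors).
    """
    m = _validate_counts(m)
    if (m.sum(axis=0) == 0).any():
        bad = m.columns[m.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has no nonzero counts")
    if quantile == "auto":
        quantile = _css_quantile_auto(m)
        if quantile < 0.25:
            warnings.warn(
                f"CSS stability scan selected a low quantile ({quantile:.2f})",
                UserWarning, stacklevel=2,
            )
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")

    factors = {}
    for name, col in m.items():
        nz = col[col > 0]
        qval = np.quantile(nz, quantile)
        factors[name] = float(col[col <= qval].sum())
    factors = pd.Series(factors, name="css_factor")
    scaled = m / factors * float(factors.median())
    if log2:
        scaled = np.log2(scaled + 1.0)
    return scaled, factors


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (nats) of one sample."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("shannon requires a positive library size")
    return float(_skbio_shannon(counts, base=np.e))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 is defined for integer counts only")
    return float(_skbio_chao1(counts.astype(int), bias_corrected=True))


def bray_curtis(m: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity matrix."""
    m = _validate_counts(m)
    if m.shape[1] < 2:
        raise ValueError("bray_curtis requires >= 2 samples")
    if (m.sum(axis=0) == 0).any():
        bad = m.columns[m.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size; distance undefined")
    d = squareform(pdist(m.to_numpy(float).T, metric="braycurtis"))
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def diversity_table(m: pd.DataFrame) -> pd.DataFrame:
    """Per-sample observed richness, Shannon H (nats) and Chao1."""
    m = _validate_counts(m)
    rows = {}
    for name, col in m.items():
        c = col.to_numpy()
        rows[name] = {
            "observed": int((c > 0).sum()),
            "shannon": shannon(c),
            "chao1": chao1(c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def diversity_association(
    diversity: pd.Series,
    trait: pd.Series,
    sex: pd.Series,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman correlation of a diversity index with a trait, overall and
    within each sex stratum.  Constant traits yield NaN rho with a flag."""
    diversity, trait = diversity.align(trait, join="inner")
    sex = sex.loc[diversity.index]
    rows = []
    strata = [("all", diversity.index)] + [
        (str(s), sex.index[sex == s]) for s in sorted(sex.unique())
    ]
    for label, idx in strata:
        if len(idx) < 3:
            raise ValueError(f"stratum {label!r} has fewer than 3 subjects")
        res = spearman(diversity.loc[idx], trait.loc[idx], method=method)
        rows.append(
            {
                "stratum": label,
                "n": len(idx),
                "rho": res.statistic,
                "pvalue": res.pvalue,
                "degenerate": res.method == "degenerate",
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


class FeatureFilter(BaseEstimator, TransformerMixin):
    """Prevalence/total-count filter over a families x samples matrix."""

    def __init__(self, min_prevalence: float = 0.10, min_total: int = 10):
        self.min_prevalence = min_prevalence
        self.min_total = min_total

    def fit(self, X, y=None):
        kept = filter_features(X, self.min_prevalence, self.min_total)
        self.kept_features_ = list(kept.index)
        return self

    def transform(self, X):
        if not hasattr(self, "kept_features_"):
            raise ValueError("FeatureFilter is not fitted")
        return pd.DataFrame(X).loc[self.kept_features_]


class CSSNormalizer(BaseEstimator, TransformerMixin):
    """Cumulative sum scaling as a transformer.

    ``fit`` resolves the quantile (running the stability scan when
    ``quantile='auto'``); ``transform`` computes per-sample factors on the
    given matrix and rescales by their median, storing them in
    ``factors_``.
    """

    def __init__(self, quantile="auto", log2: bool = False):
        self.quantile = quantile
        self.log2 = log2

    def fit(self, X, y=None):
        X = _validate_counts(X)
        self.quantile_ = (
            _css_quantile_auto(X) if self.quantile == "auto" else float(self.quantile)
        )
        return self

    def transform(self, X):
        if not hasattr(self, "quantile_"):
            raise ValueError("CSSNormalizer is not fitted")
        scaled, factors = css_normalize(X, quantile=self.quantile_, log2=self.log2)
        self.factors_ = factors
        return scaled
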