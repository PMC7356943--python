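"""Rank-based tests and small statistical utilities.

Kruskal-Wallis, Mann-Whitney and Spearman tests are provided with two
p-value paths: a tie-corrected asymptotic approximation and an exact
enumeration of the permutation null, selected automatically for small
samples.  The exact path exists because the selection procedures built on
these tests are validated against brute-force permutation oracles; the
asymptotic path matches the conventional large-sample forms.

All tests use midranks and two-sided p-values.  The Mann-Whitney normal
approximation deliberately omits the continuity correction so that, on two
groups, its p-value coincides exactly with the 1-df chi-square p-value of
the Kruskal-Wallis statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney",
    "spearman",
    "hwe_test",
    "bh_adjust",
    "roc_auc",
]

#: largest pooled sample size for which the exact path is chosen by "auto"
_EXACT_N_KW = 10
_EXACT_N_MW = 14
_EXACT_N_SPEARMAN = 8

_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str


def _tie_term(ranks: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _kw_statistic(ranks: np.ndarray, sizes: np.ndarray, tie_corr: float) -> float:
    n = ranks.size
    offset = 0
    s = 0.0
    for ni in sizes:
        r = ranks[offset : offset + ni]
        s += r.sum() ** 2 / ni
        offset += ni
    h = 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)
    return h / tie_corr


def kruskal_wallis(groups, method: str = "auto") -> TestResult:
    """Tie-corrected Kruskal-Wallis test across >= 2 groups.

    method: "auto" (exact when pooled n <= 10), "exact", or "asymptotic".
    Constant pooled data yields statistic 0 and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    sizes = np.array([a.size for a in arrays])
    ranks = sps.rankdata(pooled)
    tie_corr = 1.0 - _tie_term(ranks) / (n**3 - n) if n > 1 else 1.0
    if tie_corr <= 0:  # all observations tied
        return TestResult(0.0, 1.0, "degenerate")
    h = _kw_statistic(ranks, sizes, tie_corr)

    if method == "auto":
        method = "exact" if n <= _EXACT_N_KW else "asymptotic"
    if method == "asymptotic":
        p = float(sps.chi2.sf(h, len(arrays) - 1))
        return TestResult(float(h), p, "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    hits = 0
    total = 0
    if len(arrays) == 2:
        # rank-sum fast path: H depends only on the first group's rank sum
        n1, n2 = int(sizes[0]), int(sizes[1])
        grand = ranks.sum()
        scale = 12.0 / (n * (n + 1))
        for chosen in itertools.combinations(range(n), n1):
            r1 = ranks[list(chosen)].sum()
            r2 = grand - r1
            h_perm = (scale * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)) / tie_corr
            total += 1
            if h_perm >= h - _EPS:
                hits += 1
        return TestResult(float(h), hits / total, "exact")
    for perm_ranks in _group_assignments(ranks, sizes):
        total += 1
        if _kw_statistic(perm_ranks, sizes, tie_corr) >= h - _EPS:
            hits += 1
    return TestResult(float(h), hits / total, "exact")


def _group_assignments(ranks: np.ndarray, sizes: np.ndarray):
    """Yield rank vectors reordered over every distinct split into groups."""
    idx = np.arange(ranks.size)

    def rec(remaining: tuple, size_pos: int):
        if size_pos == len(sizes) - 1:
            yield list(remaining)
            return
        k = sizes[size_pos]
        for chosen in itertools.combinations(remaining, k):
            chosen_set = set(chosen)
            rest = tuple(i for i in remaining if i not in chosen_set)
            for tail in rec(rest, size_pos + 1):
                yield list(chosen) + tail

    for order in rec(tuple(idx), 0):
        yield ranks[np.array(order)]


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    Reports the U statistic of the first sample.  The asymptotic path uses
    the normal approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    tie = _tie_term(ranks)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "degenerate")

    if method == "auto":
        method = "exact" if n <= _EXACT_N_MW else "asymptotic"
    if method == "asymptotic":
        z = (u - mu) / np.sqrt(var)
        return TestResult(u, float(min(1.0, 2.0 * sps.norm.sf(abs(z)))), "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    dev = abs(u - mu)
    hits = 0
    total = comb(n, n1)
    for chosen in itertools.combinations(range(n), n1):
        u_perm = ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u_perm - mu) >= dev - _EPS:
            hits += 1
    return TestResult(u, hits / total, "exact")


def spearman(x, y, method: str = "auto") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Exact p enumerates all permutations of one rank vector (n <= 8 under
    "auto").  Either input constant -> statistic NaN, p NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two aligned 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return TestResult(float("nan"), float("nan"), "degenerate")

    if method == "auto":
        method = "exact" if n <= _EXACT_N_SPEARMAN else "asymptotic"
    if method == "asymptotic":
        rho, p = sps.spearmanr(x, y)
        return TestResult(float(rho), float(p), "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)
    perms = np.array(list(itertools.permutations(ryc)))
    rho_null = perms @ rxc / denom
    p = float(np.mean(np.abs(rho_null) >= abs(rho) - _EPS))
    return TestResult(rho, p, "exact")


def hwe_test(genotype_counts) -> TestResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    genotype_counts: (n_AA, n_Aa, n_aa) for the two alleles A/a.  Expected
    counts use the sample allele frequency; monomorphic samples return
    statistic 0, p = 1.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("genotype_counts must be three non-negative counts")
    n = counts.sum()
    if n == 0:
        raise ValueError("hwe_test undefined for all-zero counts")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return TestResult(0.0, 1.0, "monomorphic")
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return TestResult(chi2, float(sps.chi2.sf(chi2, 1)), "chi-square")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p, q <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(scores, labels) -> float:
    """Tie-aware ROC AUC (rank / Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("roc_auc requires exactly two classes present")
    return float(roc_auc_score(labels == classes[1], scores))
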