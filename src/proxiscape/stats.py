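"""Shared exact-test machinery.

The 2x2 tables are oriented as

    (a, b) = (labeled inside,  other expressed inside)
    (c, d) = (labeled outside, other expressed outside)

and the one-sided alternative is always enrichment of labeled in the first
row.  The orientation is fixed so results are bit-reproducible.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact test for enrichment of the first row.

    Returns the exact hypergeometric upper-tail probability
    P(X >= a | N = a+b+c+d, K = a+c, n = a+b).
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError("table cells must be non-negative")
    N = a + b + c + d
    if N == 0:
        logger.warning("degenerate all-zero 2x2 table; returning p = 1")
        return 1.0
    K = a + c  # labeled total
    n = a + b  # inside total
    # sf(a - 1) = P(X >= a)
    return float(sps.hypergeom.sf(a - 1, N, K, n))


def incidence_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared test (no continuity correction) on a 2x2 table.

    Returns (chi2 statistic, p) against the 1-df reference distribution.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("table cells must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR q-values (step-down enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_greater(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative "x > y".

    Exact enumeration when the combined sample size is <= ``exact_max_n`` and
    there are no ties; tie-corrected normal approximation otherwise (ties make
    the exact null distribution unavailable in closed form).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def rank_sum_less(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative "x < y"."""
    return rank_sum_greater(np.asarray(y, float), np.asarray(x, float), exact_max_n)
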