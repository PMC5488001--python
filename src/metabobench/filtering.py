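"""Univariate significance filtering before classification.

Dimension reduction keeps a metabolite when at least one of its pairwise
two-sample tests between phenotype groups is significant at the raw
(uncorrected) level alpha. Welch t-tests are used in the baseline
scenarios; Wilcoxon rank-sum tests, robust to the non-normal marginals of
the realistic scenarios, otherwise.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["significance_filter", "pairwise_min_pvalues"]

log = logging.getLogger(__name__)

#: default significance level of the pairwise tests
DEFAULT_ALPHA = 0.025
#: fallback size when no metabolite clears alpha
FALLBACK_KEEP = 10


def pairwise_min_pvalues(X: np.ndarray, y: np.ndarray, method: str = "t") -> np.ndarray:
    """Minimum pairwise two-sample p-value per metabolite.

    Runs all G(G-1)/2 group-pair tests per column (Welch t for
    ``method="t"``, Wilcoxon rank-sum for ``"wilcoxon"``) and returns the
    columnwise minimum. Constant-in-both-groups columns get p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before filtering")
    groups = np.unique(y)
    if groups.size < 2:
        raise ValueError("need at least two phenotype groups")
    min_p = np.ones(X.shape[1])
    for a, b in combinations(groups, 2):
        Xa, Xb = X[y == a], X[y == b]
        if min(len(Xa), len(Xb)) < 2:
            raise ValueError("need at least two samples per phenotype")
        if method == "t":
            res = stats.ttest_ind(Xa, Xb, axis=0, equal_var=False)
        elif method == "wilcoxon":
            res = stats.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided")
        else:
            raise ValueError(f"unknown method {method!r}")
        p = np.asarray(res.pvalue, dtype=float)
        # degenerate columns (zero variance in both groups) yield NaN
        p = np.where(np.isnan(p), 1.0, p)
        np.minimum(min_p, p, out=min_p)
    return min_p


def significance_filter(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "t",
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Indices of metabolites with any significant pairwise group test.

    A metabolite is kept iff its minimum pairwise p-value is below
    ``alpha`` — a single separating phenotype pair is enough to make it
    informative for multiclass discrimination. If nothing clears alpha,
    the ``FALLBACK_KEEP`` smallest-p metabolites are kept (with a warning)
    so downstream classifiers remain fittable. Returns sorted indices.
    """
    min_p = pairwise_min_pvalues(X, y, method=method)
    kept = np.flatnonzero(min_p < alpha)
    if kept.size == 0:
        k = min(FALLBACK_KEEP, min_p.size)
        log.warning(
            "no metabolite significant at alpha=%g; keeping the %d smallest p-values",
            alpha,
            k,
        )
        kept = np.sort(np.argsort(min_p, kind="stable")[:k])
    return kept
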