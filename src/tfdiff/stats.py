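"""Small statistical utilities shared across modules.

The AUROC here is the rank-based (Mann-Whitney) estimator with ties counted
as half-wins: AUROC = P(X1 > X2) + 0.5 * P(X1 = X2) for a random class-1
score X1 and class-2 score X2.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest, rankdata

__all__ = ["auroc", "folded_auroc", "auroc_rows", "folded_auroc_rows",
           "binomial_sign_test"]


def auroc(scores, labels) -> float:
    """Area under the ROC curve of `scores` for binary `labels`.

    Labels are truthy for class 1 (the positive class); higher scores are
    interpreted as more class-1-like. Ties contribute 0.5 per tied pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = labels.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("auroc requires both classes to be present")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def folded_auroc(scores, labels) -> float:
    """Direction-agnostic AUROC: max(a, 1 - a).

    Used as the selection criterion for (k-mer, region) and (PWM, region)
    variables so that enrichment in either class counts; the sign of the
    corresponding coefficient in the global model recovers the direction.
    """
    a = auroc(scores, labels)
    return max(a, 1.0 - a)


def auroc_rows(scores: np.ndarray, labels) -> np.ndarray:
    """AUROC of each row of a (m, n) score matrix against shared labels.

    Vectorized counterpart of :func:`auroc` (one ranking pass per row);
    used by the region searches, which score many candidate regions over
    the same sequences.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = labels.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("auroc requires both classes to be present")
    ranks = rankdata(scores, axis=1)
    return (ranks[:, labels].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n2)


def folded_auroc_rows(scores: np.ndarray, labels) -> np.ndarray:
    a = auroc_rows(scores, labels)
    return np.maximum(a, 1.0 - a)


def binomial_sign_test(k_successes: int, n: int) -> float:
    """Exact two-sided binomial test of k successes in n trials against p=0.5.

    Two-sidedness follows the minimum-likelihood-sum convention (sum of the
    probabilities of all outcomes no more likely than the observed one).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k_successes <= n:
        raise ValueError("k_successes must lie in [0, n]")
    return float(binomtest(k_successes, n, 0.5, alternative="two-sided").pvalue)
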