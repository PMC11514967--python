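"""Discriminative core-motif PWM learned by L1-penalized logistic regression.

Sites are the aligned K-length core occurrences (optionally with flanking
nucleotides); each site is one-hot encoded into a (K + 2*n_flank) x 4 binary
matrix, and a logistic model with one coefficient per (position, nucleotide)
cell is trained to separate the two classes. Because the penalized logistic
likelihood is convex, the fitted coefficient matrix is the optimal
discriminative PWM for perfectly aligned fixed-length sites — unlike
heuristic motif discovery on long unaligned sequences. Positive weights
favor class 1, negative weights class 2 ("mirror logo" orientation).

N positions one-hot to an all-zero row and contribute nothing to the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import LassoLogisticFit, lasso_logistic_cv, unpenalized_logistic
from .motifs import ALPHABET, PWM, AlignedSequence, encode

__all__ = ["DiscriminativePWM", "one_hot_sites", "extract_core_flank",
           "fit_discriminative_pwm", "dm_score", "two_ppm_baseline", "pwm_site_scores"]


@dataclass
class DiscriminativePWM:
    pwm: PWM  # source = "discriminative"; (K + 2*n_flank) x 4 coefficients
    intercept: float
    lasso_lambda: float
    n_flank: int
    cv: LassoLogisticFit | None = None  # None for unpenalized fits

    @property
    def weights(self) -> np.ndarray:
        return self.pwm.weights


def one_hot_sites(sites: list[str]) -> np.ndarray:
    """(n, K, 4) binary encoding; N rows are all-zero."""
    codes = np.stack([encode(s) for s in sites])
    n, K = codes.shape
    out = np.zeros((n, K, 4))
    for j in range(4):
        out[:, :, j] = codes == j
    return out


def extract_core_flank(s: AlignedSequence, n_flank: int = 4) -> str | None:
    """The (K + 2*n_flank)-length subsequence centered on the core.

    Returns None when a flank would overflow the aligned window (the caller
    drops the sequence and logs it); raises if the sequence was never
    anchored on a core occurrence.
    """
    if s.core_span is None:
        raise ValueError("sequence has no core span (skip-anchoring mode?)")
    a, b = s.core_span
    if a - n_flank < 0 or b + n_flank > len(s.seq):
        return None
    return s.seq[a - n_flank: b + n_flank]


def fit_discriminative_pwm(sites_a: list[str], sites_b: list[str], seed: int = 0,
                           n_flank: int = 0, penalized: bool = True,
                           lambda_rule: str = "min", n_folds: int = 10) -> DiscriminativePWM:
    """Fit the discriminative PWM on class-1 (`sites_a`) vs class-2 sites.

    `n_flank` is recorded as metadata only: the caller extracts core+flank
    sites of the right length. With `penalized`, lambda is chosen by
    internal cross-validation on the training sites; `penalized=False`
    gives the plain maximum-likelihood fit (used for simplicity
    comparisons).
    """
    if not sites_a or not sites_b:
        raise ValueError("both classes must be non-empty")
    sites = list(sites_a) + list(sites_b)
    K = len(sites[0])
    if any(len(s) != K for s in sites):
        raise ValueError("all sites must have the same length")
    X = one_hot_sites(sites).reshape(len(sites), -1)
    y = np.r_[np.ones(len(sites_a)), np.zeros(len(sites_b))]
    if penalized:
        fit = lasso_logistic_cv(X, y, seed=seed, n_folds=n_folds, rule=lambda_rule)
        coef, intercept, lam = fit.coef, fit.intercept, fit.lambda_
    else:
        coef, intercept = unpenalized_logistic(X, y)
        fit, lam = None, 0.0
    pwm = PWM(coef.reshape(K, 4), source="discriminative", name="DM")
    return DiscriminativePWM(pwm, intercept, lam, n_flank, cv=fit)


def dm_score(site: str | AlignedSequence, dpwm: DiscriminativePWM) -> float:
    """Eq.-style linear score sum_k sum_j a_kj * s_kj (no intercept).

    A monotone surrogate of the class-1 probability; N positions contribute 0.
    """
    if isinstance(site, AlignedSequence):
        site = extract_core_flank(site, dpwm.n_flank)
        if site is None:
            raise ValueError("flank overflows the aligned window")
    codes = encode(site)
    K = dpwm.weights.shape[0]
    if codes.size != K:
        raise ValueError(f"site length {codes.size} != PWM length {K}")
    valid = codes < 4
    return float(dpwm.weights[np.arange(K)[valid], codes[valid]].sum())


def pwm_site_scores(sites: list[str], weights: np.ndarray) -> np.ndarray:
    """Vectorized site scores for a K x 4 weight matrix (N contributes 0)."""
    codes = np.stack([encode(s) for s in sites])
    w5 = np.concatenate([weights, np.zeros((weights.shape[0], 1))], axis=1)
    return w5[np.arange(codes.shape[1])[None, :], codes].sum(axis=1)


def two_ppm_baseline(ppm1, ppm2, train_sites, train_labels, test_sites, test_labels,
                     background=(0.25, 0.25, 0.25, 0.25), pseudocount: float = 0.01) -> float:
    """Baseline: per-class PPMs -> log-odds PWMs -> 2-score logistic model.

    P(1|s) = sigmoid(a + b1*PWM1(s) + b2*PWM2(s)) fitted on training sites;
    returns the held-out AUROC. The PPMs must have been estimated on the
    training split only.
    """
    from .motifs import ppm_to_pwm
    from .stats import auroc

    w1 = ppm_to_pwm(ppm1, background, pseudocount).weights
    w2 = ppm_to_pwm(ppm2, background, pseudocount).weights
    Xtr = np.c_[pwm_site_scores(train_sites, w1), pwm_site_scores(train_sites, w2)]
    Xte = np.c_[pwm_site_scores(test_sites, w1), pwm_site_scores(test_sites, w2)]
    coef, intercept = unpenalized_logistic(Xtr, np.asarray(train_labels, dtype=float))
    return auroc(Xte @ coef + intercept, test_labels)


def mirror_logo_table(dpwm: DiscriminativePWM) -> "object":
    """Signed weight matrix as a DataFrame (positions x A,C,G,T) for export.

    Positive entries point toward class 1 in a mirror logo, negative toward
    class 2.
    """
    import pandas as pd

    return pd.DataFrame(dpwm.weights, columns=list(ALPHABET))
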