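"""L1-penalized logistic regression with a glmnet-style lambda path and CV.

The objective is (1/n) * sum logistic deviance + lambda * ||beta||_1. The
per-lambda solver is scikit-learn's liblinear (C = 1 / (n * lambda)); the
path starts at the data-derived lambda_max (smallest lambda with an all-zero
solution) and decreases geometrically. lambda is chosen by k-fold
cross-validated deviance, either at the minimum ("min") or at the sparsest
model within one standard error of it ("1se").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["LassoLogisticFit", "lasso_logistic_path", "lasso_logistic_cv", "unpenalized_logistic"]

_EPS = 1e-12


@dataclass
class LassoLogisticFit:
    coef: np.ndarray
    intercept: float
    lambda_: float
    lambdas: np.ndarray  # full path, decreasing
    path_coefs: np.ndarray  # (n_lambdas, p)
    path_intercepts: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    rule: str

    @property
    def nonzero_counts(self) -> np.ndarray:
        return (self.path_coefs != 0).sum(axis=1)

    def path_model_near(self, n_keep: int) -> tuple[int, np.ndarray, float]:
        """Path index whose nonzero count is closest to n_keep (exact when
        attained; ties resolved toward the sparser / larger-lambda model)."""
        nz = self.nonzero_counts
        gap = np.abs(nz - n_keep)
        i = int(np.argmin(gap))  # argmin takes the first (largest lambda)
        return i, self.path_coefs[i], float(self.path_intercepts[i])


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    p1 = y.mean()
    return float(np.abs(X.T @ (y - p1)).max() / len(y))


def _fit_one(X, y, lam: float) -> tuple[np.ndarray, float]:
    if lam <= 0:
        raise ValueError("lambda must be positive on the path")
    C = 1.0 / (len(y) * lam)
    m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                           fit_intercept=True, intercept_scaling=10.0,
                           tol=1e-5, max_iter=800, random_state=0)
    m.fit(X, y)
    return m.coef_[0].copy(), float(m.intercept_[0])


def lasso_logistic_path(X, y, n_lambdas: int = 30, lambda_min_ratio: float = 1e-2,
                        lambdas: np.ndarray | None = None):
    """Fit the whole lambda path; returns (lambdas, coefs, intercepts)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lmax = max(_lambda_max(X, y), _EPS)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    coefs = np.zeros((len(lambdas), X.shape[1]))
    intercepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        coefs[i], intercepts[i] = _fit_one(X, y, lam)
    return np.asarray(lambdas), coefs, intercepts


def binomial_deviance(X, y, coef, intercept) -> float:
    """Mean binomial deviance (-2/n * log-likelihood) of a linear scorer."""
    eta = X @ coef + intercept
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * ll.mean())


_deviance = binomial_deviance


def lasso_logistic_cv(X, y, seed: int = 0, n_folds: int = 10, rule: str = "1se",
                      n_lambdas: int = 30, lambda_min_ratio: float = 1e-2) -> LassoLogisticFit:
    """Path + k-fold CV on deviance; refits on all rows at the chosen lambda."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lmax = max(_lambda_max(X, y), _EPS)
    lambdas = np.geomspace(lmax * 1.0001, lmax * lambda_min_ratio, n_lambdas)
    n_folds = min(n_folds, int(np.bincount(y.astype(int)).min()))
    cv = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True, random_state=seed)
    dev = np.zeros((cv.get_n_splits(), len(lambdas)))
    for f, (tr, te) in enumerate(cv.split(X, y)):
        for i, lam in enumerate(lambdas):
            c, b = _fit_one(X[tr], y[tr], lam)
            dev[f, i] = _deviance(X[te], y[te], c, b)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
    i_min = int(np.argmin(mean))
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        ok = np.flatnonzero(mean <= mean[i_min] + se[i_min])
        i_sel = int(ok[0])  # largest lambda within one SE (path is decreasing)
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")
    _, coefs, intercepts = lasso_logistic_path(X, y, lambdas=lambdas)
    return LassoLogisticFit(coefs[i_sel].copy(), float(intercepts[i_sel]),
                            float(lambdas[i_sel]), lambdas, coefs, intercepts,
                            mean, se, rule)


def unpenalized_logistic(X, y, fit_intercept: bool = True) -> tuple[np.ndarray, float]:
    """Plain maximum-likelihood logistic fit (lambda = 0)."""
    m = LogisticRegression(C=np.inf, solver="lbfgs", fit_intercept=fit_intercept,
                           tol=1e-8, max_iter=5000)
    m.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return m.coef_[0].copy(), float(m.intercept_[0]) if fit_intercept else 0.0
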