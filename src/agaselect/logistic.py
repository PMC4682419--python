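"""Logistic regression and the rank-based AUC classifier quality score.

The classifier behind every fitness evaluation is plain maximum-likelihood
logistic regression,

    pi(x) = 1 / (1 + exp(-(b0 + b1*x1 + ... + bm*xm))),

fit by iteratively reweighted least squares (IRLS).  Quality is measured by
the area under the ROC curve, computed as the Mann-Whitney concordance
statistic with midrank tie handling: the probability that a randomly chosen
positive outranks a randomly chosen negative, ties counting one half.

The fitter is deliberately tolerant of quasi-separation: cross-validation
folds containing only eight positives occasionally separate, in which case
the iteration cap is reached and the model is returned with
``converged=False`` rather than raising — its scores still rank held-out
samples, which is all AUC needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm, rankdata

from .cohort import Cohort

__all__ = ["LRModel", "fit_logistic", "predict_prob", "compute_auc", "wald_table"]

_MAX_ITER = 25
_TOL = 1e-10
_RIDGE = 1e-8
_CLIP = 1e-12


@dataclass(frozen=True)
class LRModel:
    """A fitted logistic model over a feature subset.

    ``coefficients[j]`` multiplies the column ``subset_indices[j]`` of the
    cohort it was fit on; an empty subset is the intercept-only model.
    """

    intercept: float
    coefficients: np.ndarray
    subset_indices: tuple[int, ...]
    converged: bool
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (len(self.subset_indices),):
            raise ValueError("coefficient length must equal subset size")
        if not np.isfinite(self.intercept) or not np.isfinite(coef).all():
            raise ValueError("model parameters must be finite")
        object.__setattr__(self, "coefficients", coef)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, float]:
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    for _ in range(_MAX_ITER):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), _CLIP, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + _RIDGE * np.eye(p), grad)
        # step-halving keeps the log-likelihood monotone non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_cand = X @ cand
            ll_cand = _log_likelihood(eta_cand, y)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            converged = True
            break
        beta, eta = cand, eta_cand
        if abs(ll_cand - ll) <= _TOL * (abs(ll) + 1.0):
            ll = ll_cand
            converged = True
            break
        ll = ll_cand
    return beta, converged, ll


def fit_logistic(cohort: Cohort, subset: Sequence[int]) -> LRModel:
    """Fit a maximum-likelihood logistic model on the given feature subset.

    An empty subset fits the intercept-only model.  Raises if the training
    outcome is single-class or the subset contains duplicate indices.
    """
    idx = tuple(int(i) for i in subset)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate indices in subset")
    y = np.asarray(cohort.outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    X = np.column_stack([np.ones(cohort.n_samples), cohort.features[:, list(idx)]])
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")
    beta, converged, ll = _irls(X, y)
    return LRModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        subset_indices=idx,
        converged=converged,
        log_likelihood=ll,
    )


def predict_prob(model: LRModel, features: np.ndarray) -> np.ndarray:
    """Logistic probabilities for rows whose columns match the model subset."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != len(model.subset_indices):
        raise ValueError(
            f"expected {len(model.subset_indices)} feature columns, got {X.shape[1]}"
        )
    eta = model.intercept + X @ model.coefficients
    return expit(eta)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance statistic.

    Over all positive-negative pairs: the fraction of concordant pairs plus
    half the fraction of tied pairs.  Midranks make this exact under ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def wald_table(model: LRModel, cohort: Cohort) -> dict[str, np.ndarray]:
    """Wald z-tests for the coefficients of a fitted model.

    Returns standard errors, z statistics and two-sided p-values for the
    intercept followed by each subset coefficient, from the inverse observed
    information at the estimate.
    """
    X = np.column_stack(
        [np.ones(cohort.n_samples), cohort.features[:, list(model.subset_indices)]]
    )
    beta = np.concatenate([[model.intercept], model.coefficients])
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), _CLIP, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info + _RIDGE * np.eye(len(beta)))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return {"estimate": beta, "se": se, "z": z, "p_value": p}
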