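"""Repeated stratified cross-validation, the penalized fitness, and the
Monte-Carlo post-evaluation.

A candidate feature subset is scored by repeated balanced stratified k-fold
cross-validation of a logistic model (default 10 repeats of 5 folds): within
each repeat the folds are re-drawn, an AUC is computed per held-out fold,
fold AUCs are averaged per repeat, and repeat means are averaged into the
final AUC-bar.  The genetic search maximizes the size-penalized fitness

    f = 0                                     if n_subset > n_max
    f = AUC-bar + rho * (1 - n_subset/n_total)  otherwise

where rho rewards parsimony on a sliding scale and n_max hard-rejects
oversized subsets without fitting a single model.  After a search finishes,
the winning subset is re-scored without selection bias by a Monte-Carlo
post-evaluation: many stratified 80/20 train/validation splits, AUC averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .cohort import Cohort
from .logistic import compute_auc, fit_logistic, predict_prob

__all__ = [
    "CVSpec",
    "PenaltyConfig",
    "FitnessRecord",
    "make_stratified_folds",
    "repeated_cv_auc",
    "penalized_fitness",
    "monte_carlo_posteval",
]


@dataclass(frozen=True)
class CVSpec:
    """Repeated stratified cross-validation settings (default 10 x 5-fold)."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass(frozen=True)
class PenaltyConfig:
    """Size-penalty settings: penalty factor rho, hard cap n_max, and the
    cohort's total feature count n_total."""

    rho: float = 0.0
    n_max: int = 50
    n_total: int = 181

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0 < self.n_max <= self.n_total:
            raise ValueError("n_max must lie in (0, n_total]")


@dataclass(frozen=True)
class FitnessRecord:
    """Mean cross-validated AUC plus the penalized fitness of one subset."""

    mean_auc: float
    fitness: float
    n_subset: int


def make_stratified_folds(labels: Sequence[int], n_folds: int, rng_seed: int) -> np.ndarray:
    """Assign each sample to one of ``n_folds`` folds, stratified by class.

    Per-class counts across folds differ by at most one, so every fold holds
    the same class proportions as the whole dataset as nearly as possible.
    Deterministic in ``rng_seed``.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples, fewer than {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng_seed))
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def repeated_cv_auc(cohort: Cohort, subset: Sequence[int], cv: CVSpec) -> float:
    """Mean AUC over repeated stratified k-fold cross-validation.

    Each repeat draws a fresh fold partition; per fold a logistic model is
    fit on the remaining folds and scored on the held-out fold.  Fold AUCs
    are averaged per repeat and repeat means averaged overall.
    """
    idx = list(subset)
    if not idx:
        raise ValueError("subset must be non-empty")
    X = cohort.features[:, idx]
    y = cohort.outcome
    repeat_seeds = np.random.SeedSequence(cv.seed).generate_state(cv.n_repeats)
    repeat_means = np.empty(cv.n_repeats)
    cols = list(range(len(idx)))
    for r in range(cv.n_repeats):
        folds = make_stratified_folds(y, cv.n_folds, int(repeat_seeds[r] % (2**31)))
        fold_aucs = np.empty(cv.n_folds)
        for k in range(cv.n_folds):
            test = folds == k
            train_cohort = Cohort(
                features=X[~test],
                outcome=y[~test],
                feature_ids=tuple(map(str, cols)),
            )
            model = fit_logistic(train_cohort, cols)
            scores = predict_prob(model, X[test])
            fold_aucs[k] = compute_auc(scores, y[test])
        repeat_means[r] = fold_aucs.mean()
    return float(repeat_means.mean())


def penalized_fitness(mean_auc: float, n_subset: int, cfg: PenaltyConfig) -> float:
    """Size-penalized fitness: 0 over the cap, else AUC-bar + rho*(1 - n/n_total).

    An empty subset also scores 0 — an intercept-only model carries no
    selective information and must be culled by the search.
    """
    if n_subset < 0:
        raise ValueError("n_subset must be non-negative")
    if n_subset == 0 or n_subset > cfg.n_max:
        return 0.0
    return float(mean_auc + cfg.rho * (1.0 - n_subset / cfg.n_total))


def monte_carlo_posteval(
    cohort: Cohort,
    subset: Sequence[int],
    n_repeats: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> float:
    """Monte-Carlo post-evaluation: mean held-out AUC over repeated
    stratified train/validation splits (default 1000 repeats of 80/20).

    Splits are stratified so every validation set contains both classes even
    under heavy imbalance.
    """
    idx = list(subset)
    if not idx:
        raise ValueError("subset must be non-empty")
    X = cohort.features[:, idx]
    y = cohort.outcome
    cols = list(range(len(idx)))
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=int(seed) % (2**31)
    )
    aucs = np.empty(n_repeats)
    for r, (train, test) in enumerate(splitter.split(X, y)):
        train_cohort = Cohort(
            features=X[train], outcome=y[train], feature_ids=tuple(map(str, cols))
        )
        model = fit_logistic(train_cohort, cols)
        aucs[r] = compute_auc(predict_prob(model, X[test]), y[test])
    return float(aucs.mean())
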