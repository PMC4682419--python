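"""Multi-run orchestration, selection-frequency analysis, feature
sub-setting strategies, penalty sweeps, and random / stepwise baselines.

A single GA run yields one "solution" feature set; the study design runs the
search many times (100 runs per penalty value) and mines the collection:
how often each feature appears in the winning panels (selection frequency),
which reduced feature pools ("best half" of 181 features = 90, "best
quartile" = the top half of those = 45) support faster follow-up searches,
and how GA-selected panels compare against size-matched random panels and a
forward stepwise-AIC baseline, with a rank-sum test on the AUC
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cohort import Cohort
from .engine import AGAConfig, evolve
from .fitness import CVSpec, PenaltyConfig, monte_carlo_posteval, repeated_cv_auc
from .logistic import fit_logistic

__all__ = [
    "RunRecord",
    "SweepResult",
    "FrequencyTable",
    "run_batch",
    "selection_frequency",
    "subset_by_frequency",
    "subset_by_top_models",
    "random_baseline",
    "stepwise_aic",
    "compare_auc_distributions",
]


@dataclass(frozen=True)
class RunRecord:
    """One AGA run inside a sweep: penalty used, winning subset, its size,
    and its Monte-Carlo post-evaluation AUC."""

    run_id: int
    rho: float
    seed: int
    subset: tuple[int, ...]
    n_subset: int
    posteval_auc: float


@dataclass
class SweepResult:
    """All runs of a penalty sweep over one cohort."""

    runs: list[RunRecord]
    n_total: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view; subsets as semicolon-joined 1-based feature indices."""
        return pd.DataFrame(
            {
                "run_id": [r.run_id for r in self.runs],
                "rho": [r.rho for r in self.runs],
                "seed": [r.seed for r in self.runs],
                "size": [r.n_subset for r in self.runs],
                "auc": [r.posteval_auc for r in self.runs],
                "subset": [";".join(str(i + 1) for i in r.subset) for r in self.runs],
            }
        )


@dataclass(frozen=True)
class FrequencyTable:
    """Per-feature selection rate across the final best genomes of a sweep."""

    rates: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("selection rates must lie in [0, 1]")
        object.__setattr__(self, "rates", rates)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": np.arange(1, len(self.rates) + 1), "rate": self.rates}
        )


def run_batch(
    cohort: Cohort,
    cfg: AGAConfig,
    n_runs: int,
    penalties: Sequence[float],
    posteval_repeats: int = 1000,
    seed: int | None = None,
) -> SweepResult:
    """Execute ``n_runs`` independent AGA runs per penalty value.

    Every run gets an independent seed derived from the batch seed (default:
    ``cfg.seed``); each winning subset is re-scored without selection bias by
    :func:`monte_carlo_posteval`.  Deterministic given the batch seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    batch_seed = cfg.seed if seed is None else seed
    n_jobs = n_runs * len(penalties)
    seeds = np.random.SeedSequence(batch_seed).generate_state(2 * n_jobs) % (2**31)
    records: list[RunRecord] = []
    job = 0
    for rho in penalties:
        penalty = PenaltyConfig(rho=float(rho), n_max=cfg.penalty.n_max, n_total=cohort.n_total)
        for _ in range(n_runs):
            run_seed = int(seeds[2 * job])
            pe_seed = int(seeds[2 * job + 1])
            run_cfg = AGAConfig(
                penalty=penalty,
                cv=cfg.cv,
                k1=cfg.k1,
                k2=cfg.k2,
                population_size=cfg.population_size,
                generations=cfg.generations,
                tournament_size=cfg.tournament_size,
                init_skew=cfg.init_skew,
                lifespan=cfg.lifespan,
                seed=run_seed,
            )
            result = evolve(cohort, run_cfg)
            subset = tuple(int(i) for i in result.best_subset())
            auc = (
                monte_carlo_posteval(cohort, subset, posteval_repeats, seed=pe_seed)
                if subset
                else float("nan")
            )
            records.append(
                RunRecord(
                    run_id=job,
                    rho=float(rho),
                    seed=run_seed,
                    subset=subset,
                    n_subset=len(subset),
                    posteval_auc=auc,
                )
            )
            job += 1
    return SweepResult(runs=records, n_total=cohort.n_total)


def selection_frequency(results: SweepResult) -> FrequencyTable:
    """Fraction of runs whose winning panel contains each feature."""
    if results.n_runs < 1:
        raise ValueError("need at least one run")
    counts = np.zeros(results.n_total)
    for r in results.runs:
        counts[list(r.subset)] += 1
    return FrequencyTable(rates=counts / results.n_runs, n_runs=results.n_runs)


SubsetMode = Literal["half", "quartile"]


def _top_by_rate(rates: np.ndarray, k: int) -> np.ndarray:
    # ties at the boundary broken by lower feature index (stable sort on -rate)
    order = np.argsort(-rates, kind="stable")
    return np.sort(order[:k])


def subset_by_frequency(
    freqs: FrequencyTable,
    mode: SubsetMode | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Reduce the feature pool by selection frequency.

    ``mode="half"`` keeps the most commonly selected half of the features
    (90 of 181); ``mode="quartile"`` keeps the top half of that half (45 of
    181).  ``threshold=t`` instead keeps every feature with rate strictly
    above ``t``.  Returns sorted 0-based indices.
    """
    n_total = len(freqs.rates)
    if threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        return np.flatnonzero(freqs.rates > threshold)
    if mode == "half":
        return _top_by_rate(freqs.rates, n_total // 2)
    if mode == "quartile":
        half = _top_by_rate(freqs.rates, n_total // 2)
        sub = _top_by_rate(freqs.rates[half], len(half) // 2)
        return half[sub]
    raise ValueError("specify mode='half'/'quartile' or a threshold")


def subset_by_top_models(
    results: SweepResult,
    top_fraction: float = 0.05,
    include_best_half: bool = False,
) -> np.ndarray:
    """Union of features over the top fraction of runs by post-eval AUC.

    With ``include_best_half`` the frequency-based "best half" is unioned in
    as well, guarding against features whose value is purely combinatorial.
    """
    if results.n_runs < 1:
        raise ValueError("empty sweep result")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    k = math.ceil(top_fraction * results.n_runs)
    order = sorted(results.runs, key=lambda r: -r.posteval_auc)
    selected: set[int] = set()
    for r in order[:k]:
        selected.update(r.subset)
    if include_best_half:
        selected.update(subset_by_frequency(selection_frequency(results), mode="half"))
    return np.array(sorted(selected), dtype=int)


def random_baseline(
    cohort: Cohort,
    size: int,
    n_sets: int = 100,
    cv: CVSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated AUCs of ``n_sets`` uniformly random subsets of
    exactly ``size`` features — the chance-level comparator for GA panels."""
    if not 1 <= size <= cohort.n_total:
        raise ValueError("size must lie in [1, n_total]")
    cv = cv or CVSpec(n_folds=5, n_repeats=100)
    rng = np.random.default_rng(seed)
    # one shared CV partition seed: scores differ only through the subsets
    aucs = np.empty(n_sets)
    for i in range(n_sets):
        subset = rng.choice(cohort.n_total, size=size, replace=False)
        aucs[i] = repeated_cv_auc(cohort, subset, cv)
    return aucs


@dataclass(frozen=True)
class StepwiseStep:
    subset: tuple[int, ...]
    aic: float
    cv_auc: float | None


def stepwise_aic(
    cohort: Cohort,
    max_steps: int,
    pause_sizes: Sequence[int] = (),
    cv: CVSpec | None = None,
) -> list[StepwiseStep]:
    """Greedy forward selection minimizing AIC = 2k - 2*log-likelihood.

    At each step the candidate feature giving the lowest AIC enters if it
    lowers AIC; selection stops otherwise or at ``max_steps``.  At each size
    in ``pause_sizes`` the current subset's repeated-CV AUC is recorded.
    """
    if max_steps > cohort.n_total:
        raise ValueError("max_steps cannot exceed the feature count")
    cv = cv or CVSpec(n_folds=5, n_repeats=10)
    pauses = set(pause_sizes)
    selected: list[int] = []
    base = fit_logistic(cohort, selected)
    current_aic = 2 * 1 - 2 * base.log_likelihood
    path: list[StepwiseStep] = []
    remaining = set(range(cohort.n_total))
    for _ in range(max_steps):
        best_aic, best_j = current_aic, None
        for j in sorted(remaining):
            model = fit_logistic(cohort, selected + [j])
            aic = 2 * (len(selected) + 2) - 2 * model.log_likelihood
            if aic < best_aic - 1e-12:
                best_aic, best_j = aic, j
        if best_j is None:
            break
        selected.append(best_j)
        remaining.discard(best_j)
        current_aic = best_aic
        auc = (
            repeated_cv_auc(cohort, selected, cv) if len(selected) in pauses else None
        )
        path.append(StepwiseStep(subset=tuple(selected), aic=current_aic, cv_auc=auc))
    return path


def compare_auc_distributions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two AUC samples.

    Returns ``(U statistic, p-value)``.  AUC distributions are bounded and
    skewed, so a rank test is used rather than a t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate constant samples: rank test undefined")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
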