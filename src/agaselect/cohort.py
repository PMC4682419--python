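"""Cohort data model, CSV I/O, imputation, and the synthetic cohort generator.

The study population this package targets is a baseline blood-biomarker panel
from an aging cohort: 584 healthy-control subjects of whom 40 converted to
mild cognitive impairment or Alzheimer's disease within follow-up, measured
on 181 features (53 clinical pathology analytes, 7 circulating metals, 111
multiplex immunoassay proteins, 7 plasma measures, 3 demographics).  Access
to the original data is restricted, so :func:`generate_cohort` produces a
synthetic stand-in with the same shape, class imbalance and group structure,
with a configurable set of "planted" informative features acting through a
logistic link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_GROUP_SIZES",
    "GROUP_NAMES",
    "load_cohort",
    "save_cohort",
    "impute_missing",
    "generate_cohort",
]

#: Feature-group sizes of the emulated biomarker panel, in panel order.
DEFAULT_GROUP_SIZES: tuple[int, ...] = (53, 7, 111, 7, 3)
GROUP_NAMES: tuple[str, ...] = ("pathology", "metals", "protein", "plasma", "demographic")


class CohortFormatError(ValueError):
    """Raised when a CSV does not satisfy the cohort contract."""


@dataclass(frozen=True)
class Cohort:
    """A feature matrix with a dichotomous conversion outcome.

    Parameters
    ----------
    features
        ``(n_samples, n_total)`` float matrix; ``NaN`` marks a missing value.
    outcome
        Binary vector of length ``n_samples``; 1 = converted to MCI/AD within
        follow-up, 0 = remained cognitively healthy.
    feature_ids
        Unique identifier per feature column.
    feature_groups
        Optional category label per feature (pathology | metals | protein |
        plasma | demographic).
    """

    features: np.ndarray
    outcome: np.ndarray
    feature_ids: tuple[str, ...]
    feature_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        out = np.asarray(self.outcome)
        if feats.ndim != 2 or feats.shape[1] < 1:
            raise CohortFormatError("features must be a 2-D matrix with >= 1 column")
        if out.shape != (feats.shape[0],):
            raise CohortFormatError("outcome length must equal the number of samples")
        if not np.isin(out, (0, 1)).all():
            raise CohortFormatError("outcome values must all be 0 or 1")
        out = out.astype(np.int8)
        if out.min() == out.max():
            raise CohortFormatError("cohort must contain at least one sample of each class")
        ids = tuple(str(i) for i in self.feature_ids)
        if len(ids) != feats.shape[1]:
            raise CohortFormatError("feature_ids length must equal the number of features")
        if len(set(ids)) != len(ids):
            raise CohortFormatError("feature_ids must be unique")
        groups = self.feature_groups
        if groups is not None:
            groups = tuple(groups)
            if len(groups) != feats.shape[1]:
                raise CohortFormatError("feature_groups length must equal the number of features")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "outcome", out)
        object.__setattr__(self, "feature_ids", ids)
        object.__setattr__(self, "feature_groups", groups)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_total(self) -> int:
        return self.features.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.outcome.sum())

    def restrict(self, subset: Sequence[int]) -> "Cohort":
        """Return a cohort containing only the given feature columns."""
        idx = list(subset)
        return Cohort(
            features=self.features[:, idx],
            outcome=self.outcome,
            feature_ids=tuple(self.feature_ids[i] for i in idx),
            feature_groups=None
            if self.feature_groups is None
            else tuple(self.feature_groups[i] for i in idx),
        )


OUTCOME_COLUMN = "outcome"


def load_cohort(path: str | Path, outcome_column: str = OUTCOME_COLUMN) -> Cohort:
    """Load a cohort from a CSV file with a header row.

    Empty cells are flagged as missing (NaN); column order defines the
    feature index order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if len(set(cols)) != len(cols):
        raise CohortFormatError("duplicate column names in CSV")
    if outcome_column not in cols:
        raise CohortFormatError(f"outcome column {outcome_column!r} not found")
    out_raw = df[outcome_column]
    if out_raw.isna().any() or not out_raw.isin((0, 1)).all():
        raise CohortFormatError(f"outcome column {outcome_column!r} is not binary 0/1")
    feat_df = df.drop(columns=[outcome_column])
    return Cohort(
        features=feat_df.to_numpy(dtype=float),
        outcome=out_raw.to_numpy(dtype=int),
        feature_ids=tuple(str(c) for c in feat_df.columns),
    )


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV: feature columns by id plus an outcome column.

    Missing values are written as empty cells so a save/load round trip is
    the identity.
    """
    df = pd.DataFrame(cohort.features, columns=list(cohort.feature_ids))
    df[OUTCOME_COLUMN] = cohort.outcome
    # %.17g keeps doubles bit-exact across a save/load round trip
    df.to_csv(path, index=False, float_format="%.17g")


def impute_missing(cohort: Cohort) -> Cohort:
    """Replace missing values with the per-feature median of observed values.

    Observed values are unchanged; an all-missing column is an error.
    """
    feats = cohort.features
    if not np.isnan(feats).any():
        return cohort
    feats = feats.copy()
    for j in range(feats.shape[1]):
        col = feats[:, j]
        mask = np.isnan(col)
        if mask.all():
            raise ValueError(f"feature {cohort.feature_ids[j]!r} has no observed values")
        if mask.any():
            col[mask] = np.median(col[~mask])
    return replace(cohort, features=feats)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating model for a synthetic biomarker cohort.

    The defaults emulate the study cohort: 584 subjects, 40 converters, 181
    features in five panel groups.  ``planted_indices`` name the informative
    features; each contributes ``planted_effects`` per standardized unit to
    the log-odds of conversion.  ``intercept=None`` auto-calibrates the
    intercept so the expected number of positives equals ``n_positive``.
    Remaining features are equicorrelated Gaussian noise within their group
    at pairwise correlation ``noise_correlation``.
    """

    n_samples: int = 584
    n_positive: int = 40
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    planted_indices: tuple[int, ...] = ()
    planted_effects: tuple[float, ...] = ()
    intercept: float | None = None
    noise_correlation: float = 0.2
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes))

    def validate(self) -> None:
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not 0 < self.n_positive < self.n_samples:
            raise ValueError("n_positive must lie strictly between 0 and n_samples")
        if len(self.planted_indices) != len(self.planted_effects):
            raise ValueError("planted_indices and planted_effects must have equal length")
        if len(set(self.planted_indices)) != len(self.planted_indices):
            raise ValueError("planted_indices must be unique")
        if any(not 0 <= i < self.n_total for i in self.planted_indices):
            raise ValueError("planted_indices out of range")
        if not 0 <= self.noise_correlation < 1:
            raise ValueError("noise_correlation must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """The planted signal of a synthetic cohort (0-based indices)."""

    planted_indices: tuple[int, ...]
    planted_effects: tuple[float, ...]
    intercept: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_indices_1based": [i + 1 for i in self.planted_indices],
            "planted_effects": list(self.planted_effects),
            "intercept": self.intercept,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _calibrate_intercept(eta_no_intercept: np.ndarray, target_rate: float) -> float:
    """Bisect the intercept so mean(logistic(b0 + eta)) equals target_rate."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta_no_intercept)))))
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort from the generating model in ``spec``.

    Features are standardized equicorrelated Gaussians within panel groups.
    Outcomes are Bernoulli draws through a logistic link on the planted
    linear predictor, then nudged to exactly ``n_positive`` converters by
    flipping the labels of samples whose linear predictors sit closest to
    the decision boundary — the minimally signal-perturbing adjustment that
    matches the study's fixed cohort composition.  Identical seeds yield
    identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_total

    # noise features: equicorrelated within-group Gaussians,
    # x = sqrt(r)*z_group + sqrt(1-r)*eps; planted features are independent
    # standard normals so the correlated noise lives among the rest only
    feats = np.empty((n, m))
    r = spec.noise_correlation
    col = 0
    for size in spec.group_sizes:
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, size))
        feats[:, col : col + size] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * eps
        col += size

    idx = np.array(spec.planted_indices, dtype=int)
    eff = np.array(spec.planted_effects, dtype=float)
    if idx.size:
        feats[:, idx] = rng.standard_normal((n, idx.size))
    eta0 = feats[:, idx] @ eff if idx.size else np.zeros(n)
    if spec.intercept is None:
        b0 = _calibrate_intercept(eta0, spec.n_positive / n)
    else:
        b0 = float(spec.intercept)
    eta = b0 + eta0
    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < prob).astype(np.int8)

    # enforce the exact class count by flipping the labels least consistent
    # with their linear predictors: excess positives lose those with the
    # lowest eta, missing positives are drawn from negatives with the
    # highest eta — the minimally signal-perturbing adjustment under the
    # rare-event intercept
    excess = int(outcome.sum()) - spec.n_positive
    if excess != 0:
        source = 1 if excess > 0 else 0
        candidates = np.flatnonzero(outcome == source)
        sign = 1.0 if excess > 0 else -1.0
        order = candidates[np.argsort(sign * eta[candidates], kind="stable")]
        need = abs(excess)
        if need > order.size:
            raise RuntimeError("cannot reach the requested class count")
        outcome[order[:need]] = 1 - source
    assert int(outcome.sum()) == spec.n_positive

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        # never blank an entire column
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(n), j] = False
        feats = feats.copy()
        feats[mask] = np.nan

    ids, groups = _panel_labels(spec.group_sizes)
    cohort = Cohort(features=feats, outcome=outcome, feature_ids=ids, feature_groups=groups)
    truth = GroundTruth(tuple(int(i) for i in idx), tuple(float(e) for e in eff), b0)
    return cohort, truth


def _panel_labels(group_sizes: Sequence[int]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    names = GROUP_NAMES if len(group_sizes) == len(GROUP_NAMES) else tuple(
        f"group{k + 1}" for k in range(len(group_sizes))
    )
    ids: list[str] = []
    groups: list[str] = []
    feature_no = 0
    for name, size in zip(names, group_sizes):
        for _ in range(size):
            feature_no += 1
            ids.append(f"F{feature_no:03d}_{name}")
            groups.append(name)
    return tuple(ids), tuple(groups)
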