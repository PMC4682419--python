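import numpy as np
import pytest

from agaselect import Cohort, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100 x 6 cohort with two planted features (effects 2.0, 1.5)."""
    spec = SyntheticSpec(
        n_samples=100,
        n_positive=25,
        group_sizes=(6,),
        planted_indices=(0, 1),
        planted_effects=(2.0, 1.5),
        seed=7,
    )
    cohort, truth = generate_cohort(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """584 x 12 cohort with no planted signal, study-level imbalance."""
    spec = SyntheticSpec(n_samples=584, n_positive=40, group_sizes=(12,), seed=11)
    cohort, _ = generate_cohort(spec)
    return cohort


@pytest.fixture
def tiny_cohort():
    """Hand-built 8 x 3 cohort for exact checks."""
    rng = np.random.default_rng(3)
    return Cohort(
        features=rng.standard_normal((8, 3)),
        outcome=np.array([0, 1, 0, 1, 0, 1, 0, 1]),
        feature_ids=("a", "b", "c"),
    )


@pytest.fixture(scope="session")
def study_labels():
    """Outcome vector with the study cohort's class counts: 40 of 584."""
    y = np.zeros(584, dtype=int)
    y[:40] = 1
    return np.random.default_rng(0).permutation(y)
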