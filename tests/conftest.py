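import numpy as np
import pytest

from neuroauth import CohortSpec, LearnerConfig, generate_cohort
from neuroauth.learner import COMPACT_PROFILE_KWARGS
from neuroauth.pipeline import build_feature_pool


@pytest.fixture(scope="session")
def fast_learner_cfg():
    return LearnerConfig(seed=0, **COMPACT_PROFILE_KWARGS)


@pytest.fixture(scope="session")
def tiny_spec():
    """2 subjects x 2 days x 4 trials/task: smallest structurally complete
    cohort."""
    return CohortSpec(n_subjects=2, n_days=2, trials_per_task=4, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def small_pool():
    """Feature pool for 3 subjects x 2 days, enough for evaluation tests."""
    spec = CohortSpec(n_subjects=3, n_days=2, trials_per_task=4, seed=11)
    return build_feature_pool(generate_cohort(spec))


@pytest.fixture(scope="session")
def separable_set():
    """Two constant-offset classes of fake feature matrices: trivially
    linearly separable."""
    from neuroauth.features import FeatureMatrix
    from neuroauth.learner import LabeledSet

    rng = np.random.default_rng(5)
    feats, labels = [], []
    for y in (0, 1):
        for _ in range(8):
            P = rng.normal(0.0, 0.3, size=(10, 20)) + (4.0 if y else -4.0)
            feats.append(FeatureMatrix(P=P, row_labels=[], mode="toy"))
            labels.append(y)
    return LabeledSet(features=feats, labels=np.array(labels))
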