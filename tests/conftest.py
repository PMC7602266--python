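import numpy as np
import pytest

from emgsign.pipeline import compute_features
from emgsign.features import FeatureConfig
from emgsign.synthetic import EmgCohortConfig, generate_emg_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact multi-user cohort with the default (strong) user confounds."""
    cfg = EmgCohortConfig(n_subjects=4, n_motions=5, n_trials=6, seed=7)
    trials, confounds = generate_emg_cohort(cfg)
    return cfg, trials, confounds


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    _, trials, _ = small_cohort
    series = compute_features(trials, FeatureConfig(feature_set=("RMS", "LOG", "AAC", "PSR", "MNP", "MDF")))
    return trials, series
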