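import numpy as np
import pytest
from hypothesis import settings

from stresspipe.pipeline import cohort_features
from stresspipe.synthetic_data import GeneratorConfig, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact high-effect cohort shared across model-level tests."""
    cfg = GeneratorConfig(n_participants=5, n_blocks=10, task="MMIT",
                          stress_effect_eeg=0.8, stress_effect_hrv=0.8,
                          seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    _, sessions = small_cohort
    return cohort_features(sessions)
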