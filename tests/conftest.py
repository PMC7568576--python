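import numpy as np
import pytest
from hypothesis import settings

from cardiowave import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Eight 60-s subjects, artifact-free: shared by several test modules."""
    return syn.generate_cohort(
        {"AS": 4, "NON_AS": 4}, duration_s=60.0, fs_hz=256.0, seed=11,
        artifact_rate_per_min=0.0,
    )


@pytest.fixture(scope="session")
def planted_table():
    table, planted = syn.planted_feature_table(
        n_segments=200, n_features=200, n_informative=10, effect_size=2.0, seed=3)
    return table, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
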