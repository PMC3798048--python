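import numpy as np
import pytest

from causalbold import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Reduced cohort for fast end-to-end tests: 4 ROIs, 120 volumes."""
    return CohortConfig(
        n_per_group=5,
        n_rois=4,
        n_volumes=120,
        n_discriminative_paths=3,
        effect_size=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (18 ROIs x 460 volumes, 30 subjects)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
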