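import numpy as np
import pytest

from cogreserve import GeneratorConfig, NoiseSD, QCFailFractions, simulate_cohort


@pytest.fixture(scope="session")
def bundle300():
    """Default study-condition cohort: N=300, ~3000 mask voxels."""
    return simulate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_small():
    """Cheap cohort for unit tests: N=120 on an 8^3 grid."""
    return simulate_cohort(
        GeneratorConfig(seed=5, n_subjects=120, grid_shape=(8, 8, 8), mask_fraction=0.3)
    )


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Fully deterministic cohort: every noise SD zero, no planted QC failures."""
    return simulate_cohort(
        GeneratorConfig(
            seed=11,
            noise_sd=NoiseSD(0, 0, 0, 0, 0, 0),
            qc_fail_fractions=QCFailFractions(0, 0, 0, 0),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
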