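import numpy as np
import pytest

from dosegain.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-patient voxel-simulated cohort with one planted outlier."""
    config = GeneratorConfig(n_patients=10, seed=7, n_voxels=2500, n_outliers=1)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
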