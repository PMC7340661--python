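import numpy as np
import pytest

from tpgmodel import CohortConfig, sample_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Training-shaped cohort with the oracle noise switched off."""
    return sample_cohort(CohortConfig(seed=42, noise_sd_mmhg=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Training-shaped cohort under default (log-normal) residual noise."""
    return sample_cohort(CohortConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
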