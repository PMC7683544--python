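import numpy as np
import pytest

import rumenadapt as ra


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at reference conditions (8 goats x 9 days)."""
    meas, truth = ra.generate_cohort(ra.default_params(seed=1))
    return meas, truth


@pytest.fixture(scope="session")
def descriptors(default_cohort):
    """Step-1 synthetic-variable table for the default cohort."""
    meas, _ = default_cohort
    return ra.fit_all(ra.annotate_schedule(meas))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
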