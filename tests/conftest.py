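import numpy as np
import pytest

import radiogen_psp as r


@pytest.fixture(scope="session")
def small_cohort():
    """One small-profile synthetic cohort shared by read-only tests."""
    return r.generate_dataset(r.small_profile(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
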