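import numpy as np
import pytest

from xmodal.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Latent-mode cohort small enough for fast unit tests."""
    return generate_cohort(CohortSpec(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """The 188-patient default fixture."""
    return generate_cohort(CohortSpec(seed=11))
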