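import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20180601)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 1, n 457)."""
    from iodine_status.cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n=457, seed=1))
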