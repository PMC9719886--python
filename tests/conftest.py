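import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dectrod import default_cohort_config, derive_columns, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_10k():
    """Default-configuration cohort at n=10,000 (shared across tests)."""
    return generate_cohort(default_cohort_config(10_000, seed=1))


@pytest.fixture(scope="session")
def derived_10k(cohort_10k):
    """The same cohort with derived spectral and ROD columns."""
    return derive_columns(cohort_10k)


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient cohort for cheaper structural checks."""
    return derive_columns(generate_cohort(default_cohort_config(600, seed=7)))
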