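import numpy as np
import pytest

from mdesim import (
    AttributeProfile,
    PopulationSpec,
    SimulationConfig,
    published_recovery,
    published_recurrence,
)
from mdesim.synth import generate_survey


@pytest.fixture(scope="session")
def recovery_params():
    return published_recovery()


@pytest.fixture(scope="session")
def recurrence_params():
    return published_recurrence()


@pytest.fixture(scope="session")
def small_cohort_config(recovery_params, recurrence_params):
    return SimulationConfig(
        recovery=recovery_params,
        recurrence=recurrence_params,
        n_entities_per_profile=50,
        seed=7,
    )


@pytest.fixture(scope="session")
def big_survey():
    """One large synthetic respondent table shared by the regression tests."""
    return generate_survey(PopulationSpec(n_respondents=50_000, seed=42))


@pytest.fixture
def reference_profile():
    return AttributeProfile("12-18")
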