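import numpy as np
import pytest

from hbocsim import (
    AgeDistribution,
    CohortModel,
    default_schedules,
    packaged_fixture_paths,
    read_fixture,
)


@pytest.fixture(scope="session")
def schedules():
    return default_schedules()


@pytest.fixture(scope="session")
def curves(schedules):
    from hbocsim import cumulative_from_hazard

    return {key: cumulative_from_hazard(s) for key, s in schedules.items()}


@pytest.fixture(scope="session")
def study_fixture_data():
    return read_fixture(packaged_fixture_paths())


@pytest.fixture(scope="session")
def synthetic_model(schedules):
    """Cohort model on the default truncated-normal simulation population."""
    dist = AgeDistribution.truncated_normal(186_537)
    return CohortModel(dist, schedules)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
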