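import logging

import pytest

from edflow.estimators import MultistateCox
from edflow.expand import expand_to_long
from edflow.simulate import SimulationConfig, sample_cohort

logging.getLogger("edflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort():
    """Moderate synthetic cohort under the default (study-like) conditions."""
    return sample_cohort(SimulationConfig(n=3000, seed=11))


@pytest.fixture(scope="session")
def long_table(cohort):
    return expand_to_long(cohort)


@pytest.fixture(scope="session")
def fitted_model(long_table):
    return MultistateCox().fit(long_table)


@pytest.fixture
def reference_profile():
    return {
        "age": 1, "gender": "Male", "ethnicity": "Not Hispanic", "race": "White",
        "time_of_day": "16:00-20:00", "season": "Winter", "n_physicians": 8,
        "esi": 4,
    }
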