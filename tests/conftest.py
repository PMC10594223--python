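import logging
import warnings

import pytest
from hypothesis import HealthCheck, settings

import trialcea as tc

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

logging.getLogger("trialcea").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="FMI .* still above")


@pytest.fixture(scope="session")
def small_config():
    return tc.TrialConfig(cell_sizes=(12, 12, 12, 14), n_sites=3, seed=11)


@pytest.fixture(scope="session")
def small_complete(small_config):
    return tc.generate_trial(small_config)


@pytest.fixture(scope="session")
def small_masked(small_config, small_complete):
    return tc.inject_missingness(small_complete, small_config)


@pytest.fixture(scope="session")
def paper_config():
    """The default study conditions: cells 49/49/47/55, paper follow-up."""
    return tc.TrialConfig(seed=17)


@pytest.fixture(scope="session")
def value_set():
    return tc.example_value_set()


@pytest.fixture(scope="session")
def unit_costs():
    return tc.default_unit_costs()


@pytest.fixture(scope="session")
def wages():
    return tc.WageSchedule()
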