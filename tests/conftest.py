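import warnings

import pytest

from rnadriver.normalize import normalize_pipeline
from rnadriver.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def bundle(default_config):
    """One default cohort shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(default_config, seed=11)


@pytest.fixture(scope="session")
def normalized(bundle):
    return normalize_pipeline(bundle.counts)
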