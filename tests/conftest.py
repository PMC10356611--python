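import numpy as np
import pytest

from eggsearch import ChamberSpec, DriftParams, simulate_session


@pytest.fixture(scope="session")
def chamber():
    return ChamberSpec()


@pytest.fixture(scope="session")
def default_params():
    return DriftParams()


@pytest.fixture(scope="session")
def small_cohort(default_params, chamber):
    """Twenty simulated flies, one hour each (shared across tests)."""
    return [
        simulate_session(default_params, chamber, 3600.0, seed=9000 + i)
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def long_session(default_params, chamber):
    """One two-hour session used by pipeline-level tests."""
    return simulate_session(default_params, chamber, 7200.0, seed=4242)
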