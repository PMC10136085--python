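import pytest

import dsdctrl as d
from dsdctrl.config import load_scheme


@pytest.fixture(scope="session")
def integral_params():
    return d.IntegralCircuitParams()


@pytest.fixture(scope="session")
def integral_circuit(integral_params):
    return d.build_integral_circuit(integral_params)


@pytest.fixture(scope="session")
def statefb_params():
    return d.StateFeedbackParams()


@pytest.fixture(scope="session")
def statefb_circuit(statefb_params):
    return d.build_state_feedback_circuit(statefb_params)


@pytest.fixture(scope="session")
def integral_scheme():
    return load_scheme("integral_default")


@pytest.fixture(scope="session")
def statefb_scheme():
    return load_scheme("state_feedback_default")
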