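import numpy as np
import pytest

from hcodb.model import default_model, canonical_parameters
from hcodb.simulate import (SimulationProtocol, canonical_initial_conditions,
                            simulate_instance)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def protocol():
    return SimulationProtocol()


@pytest.fixture(scope="session")
def canonical_ics(protocol):
    """Shared initial conditions from the 200 s canonical warm-up."""
    return canonical_initial_conditions(proto=protocol)


@pytest.fixture(scope="session")
def canonical_trace(protocol, canonical_ics):
    """The canonical instance, run through the full settle+record protocol."""
    return simulate_instance(canonical_parameters(), canonical_ics, protocol)


@pytest.fixture(scope="session")
def canonical_metrics(canonical_trace, protocol):
    from hcodb.classify import metrics_from_trace

    return metrics_from_trace(canonical_trace, window=(0.0, protocol.record))
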