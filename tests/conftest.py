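import numpy as np
import pytest

from petflux.input_function import PopulationInputFunction
from petflux.cli_io import load_fixture_outcomes


@pytest.fixture(scope="session")
def pop():
    return PopulationInputFunction()


@pytest.fixture(scope="session")
def grid():
    return np.arange(0.0, 90.0 + 1e-9, 0.1)


@pytest.fixture(scope="session")
def outcomes():
    """Packaged 12-patient baseline/week-8 outcomes table."""
    return load_fixture_outcomes()


@pytest.fixture(scope="session")
def reference_labels(outcomes):
    return dict(zip(outcomes["patient_id"], outcomes["reference"]))
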