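import numpy as np
import pytest

from trnsim.params import default_parameters
from trnsim.trn_cell import SolverConfig, initial_state


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def rest_state(params):
    """Settled resting state shared across tests (expensive)."""
    from trnsim.trn_cell import settle_to_rest
    state, diag = settle_to_rest(params, 2000.0)
    return state, diag


@pytest.fixture()
def quick_solver():
    return SolverConfig(rtol=1e-6, sample_dt=0.1)


@pytest.fixture()
def nominal_state(params):
    return initial_state(params)
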