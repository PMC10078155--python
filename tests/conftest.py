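import numpy as np
import pytest

from mepdsim.experiments import run_direction_table
from mepdsim.kndy_model import ArcInput, KndyParams, simulate
from mepdsim.mepd_circuit import MepdParams


@pytest.fixture(scope="session")
def kndy_params() -> KndyParams:
    return KndyParams()


@pytest.fixture(scope="session")
def mepd_params() -> MepdParams:
    return MepdParams()


@pytest.fixture(scope="session")
def control_trajectory(kndy_params):
    """KNDy core under the calibrated basal inhibitory tone, settled."""
    mepd = MepdParams()
    from mepdsim.mepd_circuit import mepd_output, mepd_steady_state

    inp = mepd_output(mepd_steady_state(mepd), mepd)
    return simulate(kndy_params, inp, (0.0, 600.0), dt_out=0.1)


@pytest.fixture(scope="session")
def scan(kndy_params):
    """Regime scan of the excitatory channel at a fixed inhibitory tone
    chosen so the grid spans all three regimes (computed once)."""
    from mepdsim.kndy_model import scan_input

    return scan_input(kndy_params, np.linspace(0.0, 1.2, 25), I_inh=0.5)


@pytest.fixture(scope="session")
def direction_table(kndy_params, mepd_params):
    """The eight-arm qualitative outcome table (computed once)."""
    return run_direction_table(kndy_params, mepd_params).set_index("arm")
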