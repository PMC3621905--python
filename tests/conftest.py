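import numpy as np
import pytest

from cgcell.kinetics import ChannelSpec, KineticScheme, RateLaw
from cgcell.library import channel_library
from cgcell.membrane import CellScenario, Compartment
from cgcell.workbench import build_scenario


@pytest.fixture(scope="session")
def library():
    return channel_library()


@pytest.fixture(scope="session")
def control_scenario():
    return build_scenario("Control")


@pytest.fixture(scope="session")
def rnai_scenario():
    return build_scenario("mDPP6_RNAi")


@pytest.fixture(scope="session")
def dtask3_scenario():
    return build_scenario("CG_dTASK3")


@pytest.fixture(scope="session")
def isar_scenario():
    return build_scenario("CG_ISAR")


@pytest.fixture
def two_state():
    """Symmetric two-state gate with voltage-independent rate k = 0.3/ms."""
    return KineticScheme(
        [("C", "closed"), ("O", "open")],
        [("C", "O", RateLaw(0.3)), ("O", "C", RateLaw(0.3))],
        name="sym2",
    )


@pytest.fixture
def three_chain():
    """Linear three-state chain with distinct voltage-dependent rates."""
    return KineticScheme(
        [("C", "closed"), ("O", "open"), ("I", "inactivated")],
        [
            ("C", "O", RateLaw(0.5, 0.02)),
            ("O", "C", RateLaw(0.2, -0.01)),
            ("O", "I", RateLaw(0.05, 0.03)),
            ("I", "O", RateLaw(0.01, -0.04)),
        ],
        name="chain3",
    )


@pytest.fixture
def passive_cell():
    leak = ChannelSpec("leak", None, 2.0, "nS", -70.0)
    return CellScenario("passive", Compartment(), (leak,))


@pytest.fixture(scope="session")
def test_voltages():
    return np.array([-120.0, -80.0, -40.0, 0.0, 40.0])
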