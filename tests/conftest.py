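import pytest

from fluidloop.clock import SimulatedClock
from fluidloop.kinematics import STANDARD_SYRINGES, PumpConfig, SyringeSpec
from fluidloop.network import SimulatedBus


@pytest.fixture
def half_ul_syringe() -> SyringeSpec:
    """Barrel with cross-section exactly 100.000 mm^2, so the default
    drivetrain (200 steps/rev, 1 mm lead, gear 1) gives 0.5 uL/step."""
    return SyringeSpec(
        inner_diameter=11.283791670955125,  # 2*sqrt(100/pi)
        capacity=5000.0,
        plunger_travel=57.0,
        label="100mm2",
    )


@pytest.fixture
def default_pump() -> PumpConfig:
    return PumpConfig()


@pytest.fixture
def clock() -> SimulatedClock:
    return SimulatedClock()


@pytest.fixture
def bus(clock) -> SimulatedBus:
    return SimulatedBus(clock)


@pytest.fixture
def loaded_bus(bus) -> SimulatedBus:
    """Bus with four 5 mL pumps at addresses 0-3."""
    for addr in range(4):
        bus.attach_pump(addr, STANDARD_SYRINGES["5mL"], PumpConfig(address=addr))
    return bus
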