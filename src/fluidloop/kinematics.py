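"""Syringe-pump kinematics.

Converts between commanded volumes / flow rates and stepper-motor steps /
step timing, and simulates physically plausible dispense errors so the
calibration analysis can run without hardware.

Units are fixed throughout the package: lengths in mm, volumes in uL,
flow rates in uL/min, step periods in ms. 1 mm^3 == 1 uL. No unit
inference is performed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CapacityExceededError,
    InvalidArgumentError,
    InvalidConfigurationError,
)

#: Default drivetrain constants. These are explicit, generic stepper-motor
#: defaults (NEMA-class 200 steps/rev, 1 mm lead screw, direct drive) --
#: NOT measured values for any particular hardware build.
DEFAULT_STEPS_PER_REVOLUTION = 200
DEFAULT_LEAD_PITCH_MM = 1.0
DEFAULT_GEAR_RATIO = 1.0

#: Geometry consistency tolerance: capacity must not exceed the swept
#: cylinder volume by more than this relative margin.
_GEOMETRY_TOLERANCE = 0.05


@dataclass(frozen=True)
class SyringeSpec:
    """Geometry of one syringe.

    Parameters
    ----------
    inner_diameter : float
        Barrel inner diameter in mm.
    capacity : float
        Usable volume in uL.
    plunger_travel : float
        Usable plunger travel in mm.
    label : str
        Free-text identifier used in logs and calibration reports.
    """

    inner_diameter: float
    capacity: float
    plunger_travel: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise InvalidConfigurationError(
                f"inner_diameter must be > 0, got {self.inner_diameter}"
            )
        if self.capacity <= 0:
            raise InvalidConfigurationError(f"capacity must be > 0, got {self.capacity}")
        if self.plunger_travel <= 0:
            raise InvalidConfigurationError(
                f"plunger_travel must be > 0, got {self.plunger_travel}"
            )
        swept = self.cross_section_area * self.plunger_travel
        if self.capacity > swept * (1.0 + _GEOMETRY_TOLERANCE):
            raise InvalidConfigurationError(
                f"capacity {self.capacity} uL inconsistent with swept volume "
                f"{swept:.1f} uL (diameter {self.inner_diameter} mm x travel "
                f"{self.plunger_travel} mm)"
            )

    @property
    def cross_section_area(self) -> float:
        """Barrel cross-section area in mm^2."""
        return math.pi * self.inner_diameter**2 / 4.0


@dataclass(frozen=True)
class PumpConfig:
    """Drivetrain constants of one pump unit.

    ``gear_ratio`` is motor revolutions per lead-screw revolution; values
    above 1 gear the motor down (finer steps).
    """

    steps_per_revolution: int = DEFAULT_STEPS_PER_REVOLUTION
    lead_pitch: float = DEFAULT_LEAD_PITCH_MM
    gear_ratio: float = DEFAULT_GEAR_RATIO
    address: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_revolution < 1:
            raise InvalidConfigurationError(
                f"steps_per_revolution must be >= 1, got {self.steps_per_revolution}"
            )
        if self.lead_pitch <= 0:
            raise InvalidConfigurationError(f"lead_pitch must be > 0, got {self.lead_pitch}")
        if self.gear_ratio <= 0:
            raise InvalidConfigurationError(f"gear_ratio must be > 0, got {self.gear_ratio}")
        if not 0 <= self.address <= 127:
            raise InvalidConfigurationError(
                f"address must be in [0, 127], got {self.address}"
            )


def step_volume(syringe: SyringeSpec, pump: PumpConfig) -> float:
    """Volume dispensed by a single motor step, in uL.

    One motor step advances the lead screw by
    ``lead_pitch / (gear_ratio * steps_per_revolution)`` mm; multiplied by
    the barrel cross-section this gives the per-step volume.
    """
    travel_per_step = pump.lead_pitch / (pump.gear_ratio * pump.steps_per_revolution)
    return travel_per_step * syringe.cross_section_area


def volume_to_steps(volume: float, syringe: SyringeSpec, pump: PumpConfig) -> int:
    """Number of motor steps for ``volume`` uL, round-half-to-even.

    Raises
    ------
    InvalidArgumentError
        If ``volume`` is negative.
    CapacityExceededError
        If ``volume`` exceeds the syringe capacity.
    """
    if volume < 0:
        raise InvalidArgumentError(f"volume must be >= 0, got {volume}")
    if volume > syringe.capacity:
        raise CapacityExceededError(
            f"volume {volume} uL exceeds syringe capacity {syringe.capacity} uL"
        )
    sv = step_volume(syringe, pump)
    # Banker's rounding keeps quantization bias symmetric around zero.
    return int(round(volume / sv))


def steps_to_volume(steps: int, syringe: SyringeSpec, pump: PumpConfig) -> float:
    """Volume in uL dispensed by ``steps`` motor steps."""
    if steps < 0:
        raise InvalidArgumentError(f"steps must be >= 0, got {steps}")
    return steps * step_volume(syringe, pump)


def flow_rate_to_step_period(rate: float, syringe: SyringeSpec, pump: PumpConfig) -> float:
    """Step period in ms realizing a flow rate of ``rate`` uL/min."""
    if rate <= 0:
        raise InvalidArgumentError(f"rate must be > 0, got {rate}")
    return 60_000.0 * step_volume(syringe, pump) / rate


@dataclass
class DispenseErrorModel:
    """Stochastic model of dispense error for the pump simulator.

    Error terms compose in a fixed order: diameter tolerance (one factor
    per pump, drawn at construction) -> step quantization -> per-step
    jitter -> backlash on direction change. With every term zero (and
    quantization off) the model is the identity.

    Two models built with the same parameters and seed produce identical
    dispense sequences.

    Parameters
    ----------
    step_quantization : bool
        Quantize the commanded volume to whole motor steps.
    per_step_jitter_sd : float
        SD of the per-step volume error, as a fraction of the step volume.
        Independent across steps, so the aggregate SD of an n-step dispense
        grows as sqrt(n).
    diameter_tolerance : float
        SD of the relative barrel-diameter error. A single relative
        diameter offset is drawn per model instance (it is a property of
        the physical pump+syringe, not of one dispense).
    backlash_steps : int
        Steps lost when the drivetrain reverses direction.
    seed : int
        Seeds all randomness in the model.
    fixed_volume_scale : float or None
        Testing hook: when set, use this exact multiplicative volume
        scale instead of drawing one from ``diameter_tolerance``.
    """

    step_quantization: bool = True
    per_step_jitter_sd: float = 0.0
    diameter_tolerance: float = 0.0
    backlash_steps: int = 0
    seed: int = 0
    fixed_volume_scale: float | None = None

    _rng: np.random.Generator = field(init=False, repr=False, compare=False)
    _volume_scale: float = field(init=False, repr=False, compare=False)
    _last_direction: int = field(init=False, default=0, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.per_step_jitter_sd < 0 or self.diameter_tolerance < 0:
            raise InvalidArgumentError("relative error terms must be >= 0")
        if self.backlash_steps < 0:
            raise InvalidArgumentError("backlash_steps must be >= 0")
        self.reset()

    def reset(self) -> None:
        """Re-seed the model, replaying the same error sequence."""
        self._rng = np.random.default_rng(self.seed)
        if self.fixed_volume_scale is not None:
            self._volume_scale = float(self.fixed_volume_scale)
        else:
            # Diameter error d -> (1+d); volume scales with diameter^2.
            delta = self.diameter_tolerance * self._rng.standard_normal()
            self._volume_scale = (1.0 + delta) ** 2
        self._last_direction = 0

    @property
    def volume_scale(self) -> float:
        """Multiplicative true-volume scale induced by diameter error."""
        return self._volume_scale


def simulate_dispense(
    nominal: float,
    syringe: SyringeSpec,
    pump: PumpConfig,
    model: DispenseErrorModel,
    direction: int = 1,
    correction: float = 1.0,
) -> float:
    """Simulate one dispense and return the measured volume in uL.

    Stands in for weighing the dispensed water on an analytical scale
    (density 1.000 g/mL). ``correction`` is a multiplicative factor applied
    to the commanded volume before step conversion, as produced by
    :func:`fluidloop.calibration.fit_calibration` (pass ``1/factor``).

    Successive calls on the same model draw fresh jitter; call
    :meth:`DispenseErrorModel.reset` (or rebuild the model) to replay.
    """
    if direction not in (-1, 1):
        raise InvalidArgumentError(f"direction must be +1 or -1, got {direction}")
    commanded = nominal * correction
    if model.step_quantization:
        steps = volume_to_steps(commanded, syringe, pump)
    else:
        if commanded < 0:
            raise InvalidArgumentError(f"volume must be >= 0, got {commanded}")
        if commanded > syringe.capacity:
            raise CapacityExceededError(
                f"volume {commanded} uL exceeds capacity {syringe.capacity} uL"
            )
        steps = commanded / step_volume(syringe, pump)

    sv = step_volume(syringe, pump)
    true_sv = sv * model.volume_scale
    measured = steps * true_sv

    if model.per_step_jitter_sd > 0 and steps > 0:
        # Independent per-step errors aggregate with sd ~ sqrt(n).
        agg_sd = model.per_step_jitter_sd * math.sqrt(steps) * true_sv
        measured += agg_sd * model._rng.standard_normal()

    if model.backlash_steps > 0:
        if model._last_direction != 0 and model._last_direction != direction:
            measured -= model.backlash_steps * true_sv
        model._last_direction = direction

    return max(measured, 0.0)


# Convenience geometries for the three syringe classes used in the
# calibration plans (1, 5 and 10 mL). Diameters follow typical plastic
# syringe barrels; capacities are consistent with travel to <5%.
STANDARD_SYRINGES: dict[str, SyringeSpec] = {
    "1mL": SyringeSpec(inner_diameter=4.78, capacity=1000.0, plunger_travel=57.0, label="1mL"),
    "5mL": SyringeSpec(inner_diameter=12.06, capacity=5000.0, plunger_travel=44.5, label="5mL"),
    "10mL": SyringeSpec(inner_diameter=14.5, capacity=10000.0, plunger_travel=61.0, label="10mL"),
}
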