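"""Pump dispense characterization: accuracy, precision and calibration.

Accuracy is the mean dispense error as a percentage of the nominal volume;
precision is the sample standard deviation (n-1 denominator) of the same
relative error. A characterization passes when both stay at or below the
bound (default 5% of nominal) in every tested condition.

Measured volumes come either from weighing on an analytical scale
(mass -> volume at water density 1.000 g/mL) via a CSV table, or from the
dispense simulator. The cross-condition ANOVA is deliberately not
reimplemented here; :func:`measurements_to_frame` exports a tidy table any
statistics package can consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientReplicatesError,
    InvalidArgumentError,
    InvalidDesignError,
    InvalidGroupingError,
)
from .kinematics import (
    DispenseErrorModel,
    PumpConfig,
    SyringeSpec,
    simulate_dispense,
)

DEFAULT_BOUND_PCT = 5.0


@dataclass(frozen=True)
class DispenseMeasurement:
    """One (nominal, measured) dispense pair."""

    pump: int
    syringe: str
    nominal: float     # uL
    measured: float    # uL
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise InvalidArgumentError(f"nominal must be > 0, got {self.nominal}")
        if self.measured < 0:
            raise InvalidArgumentError(f"measured must be >= 0, got {self.measured}")


@dataclass(frozen=True)
class ConditionResult:
    syringe: str
    nominal: float
    n: int
    accuracy_pct: float
    precision_pct: Optional[float]  # None when n < 2
    flag: str = ""


@dataclass(frozen=True)
class CalibrationReport:
    conditions: tuple[ConditionResult, ...]
    bound_pct: float
    passed: bool

    @property
    def worst_accuracy_pct(self) -> float:
        return max(abs(c.accuracy_pct) for c in self.conditions)

    @property
    def worst_precision_pct(self) -> float:
        vals = [c.precision_pct for c in self.conditions if c.precision_pct is not None]
        return max(vals) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "syringe": [c.syringe for c in self.conditions],
                "nominal_ul": [c.nominal for c in self.conditions],
                "n": [c.n for c in self.conditions],
                "accuracy_pct": [c.accuracy_pct for c in self.conditions],
                "precision_pct": [c.precision_pct for c in self.conditions],
                "flag": [c.flag for c in self.conditions],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Dispense characterization ({len(self.conditions)} conditions, "
            f"bound {self.bound_pct:.1f}% of nominal)",
        ]
        for c in self.conditions:
            prec = "n/a" if c.precision_pct is None else f"{c.precision_pct:6.3f}%"
            lines.append(
                f"  {c.syringe:>6s} {c.nominal:7.1f} uL  n={c.n:<3d} "
                f"accuracy {c.accuracy_pct:+7.3f}%  precision {prec}"
                + (f"  [{c.flag}]" if c.flag else "")
            )
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def _check_grouping(measurements: Sequence[DispenseMeasurement]) -> float:
    if not measurements:
        raise InvalidArgumentError("at least one measurement required")
    nominals = {m.nominal for m in measurements}
    if len(nominals) != 1:
        raise InvalidGroupingError(
            f"one condition must share a single nominal volume, got {sorted(nominals)}"
        )
    return next(iter(nominals))


def accuracy(measurements: Sequence[DispenseMeasurement]) -> float:
    """Mean dispense error as % of the shared nominal volume."""
    nominal = _check_grouping(measurements)
    errors = np.array([m.measured - m.nominal for m in measurements])
    return 100.0 * float(errors.mean()) / nominal


def precision(measurements: Sequence[DispenseMeasurement]) -> float:
    """Sample SD (n-1) of the dispense error as % of the nominal volume."""
    nominal = _check_grouping(measurements)
    if len(measurements) < 2:
        raise InsufficientReplicatesError("precision needs >= 2 replicates")
    errors = np.array([m.measured - m.nominal for m in measurements])
    return 100.0 * float(errors.std(ddof=1)) / nominal


def fit_calibration(
    measurements: Sequence[DispenseMeasurement],
    pump: Optional[PumpConfig] = None,
) -> float:
    """Least-squares slope of measured vs. nominal through the origin.

    The returned factor multiplies the effective step volume; commanding
    ``volume / factor`` (see ``correction=1/factor`` in
    :func:`~fluidloop.kinematics.simulate_dispense`) cancels the bias.
    """
    if not measurements:
        raise InvalidArgumentError("at least one measurement required")
    nominals = np.array([m.nominal for m in measurements])
    measured = np.array([m.measured for m in measurements])
    if len(np.unique(nominals)) < 2:
        raise InvalidDesignError(
            "calibration requires measurements spanning >= 2 distinct nominal volumes"
        )
    return float(np.dot(nominals, measured) / np.dot(nominals, nominals))


@dataclass(frozen=True)
class CharacterizationPlan:
    """Conditions x replicates for a simulated characterization run."""

    nominals: tuple[float, ...] = (50.0, 100.0, 300.0, 500.0)
    syringes: tuple[str, ...] = ("1mL", "5mL", "10mL")
    replicates: int = 10

    def __post_init__(self) -> None:
        if not self.nominals or not self.syringes or self.replicates < 1:
            raise InvalidArgumentError("characterization plan must be non-empty")


def run_plan(
    plan: CharacterizationPlan,
    syringes: dict[str, SyringeSpec],
    model_factory,
    pump_config: Optional[PumpConfig] = None,
) -> list[DispenseMeasurement]:
    """Simulate every dispense in the plan.

    ``model_factory(pump_index, syringe_label)`` returns the
    :class:`DispenseErrorModel` for that pump+syringe pairing, so each
    physical unit keeps its own diameter-error draw.
    """
    pump_config = pump_config or PumpConfig()
    measurements = []
    for pump_index, label in enumerate(plan.syringes):
        syringe = syringes[label]
        model = model_factory(pump_index, label)
        for nominal in plan.nominals:
            for rep in range(plan.replicates):
                measured = simulate_dispense(nominal, syringe, pump_config, model)
                measurements.append(
                    DispenseMeasurement(
                        pump=pump_index,
                        syringe=label,
                        nominal=nominal,
                        measured=measured,
                        replicate=rep,
                    )
                )
    return measurements


def characterize(
    measurements: Sequence[DispenseMeasurement],
    bound_pct: float = DEFAULT_BOUND_PCT,
) -> CalibrationReport:
    """Group measurements by (syringe, nominal) condition and evaluate the
    accuracy/precision pass flag against ``bound_pct``.

    Conditions with a single replicate are flagged, not fatal.
    """
    if not measurements:
        raise InvalidArgumentError("no measurements to characterize")
    groups: dict[tuple[str, float], list[DispenseMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.syringe, m.nominal), []).append(m)

    conditions = []
    passed = True
    for (syr, nominal), group in sorted(groups.items()):
        acc = accuracy(group)
        if len(group) >= 2:
            prec = precision(group)
            flag = ""
        else:
            prec, flag = None, "insufficient replicates for precision"
        worst = max(abs(acc), prec if prec is not None else 0.0)
        if worst > bound_pct or prec is None:
            passed = False
        conditions.append(
            ConditionResult(
                syringe=syr, nominal=nominal, n=len(group),
                accuracy_pct=acc, precision_pct=prec, flag=flag,
            )
        )
    return CalibrationReport(conditions=tuple(conditions), bound_pct=bound_pct, passed=passed)


def default_error_model_factory(
    seed: int = 42,
    per_step_jitter_sd: float = 0.003,
    diameter_tolerance: float = 0.01,
):
    """Post-calibration error model: step quantization, 0.3% per-step
    jitter, 1% residual diameter tolerance. One independent model (hence
    one diameter draw) per pump+syringe pairing."""

    def factory(pump_index: int, label: str) -> DispenseErrorModel:
        sub_seed = int(np.random.SeedSequence([seed, pump_index]).generate_state(1)[0])
        return DispenseErrorModel(
            step_quantization=True,
            per_step_jitter_sd=per_step_jitter_sd,
            diameter_tolerance=diameter_tolerance,
            seed=sub_seed,
        )

    return factory


def measurements_to_frame(measurements: Sequence[DispenseMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pump": [m.pump for m in measurements],
            "syringe": [m.syringe for m in measurements],
            "nominal_ul": [m.nominal for m in measurements],
            "measured_ul": [m.measured for m in measurements],
            "replicate": [m.replicate for m in measurements],
        }
    )


def measurements_from_frame(df: pd.DataFrame) -> list[DispenseMeasurement]:
    return [
        DispenseMeasurement(
            pump=int(r.pump),
            syringe=str(r.syringe),
            nominal=float(r.nominal_ul),
            measured=float(r.measured_ul),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
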