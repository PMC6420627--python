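"""Declarative fluid-exchange protocols and their execution.

A :class:`Protocol` is an ordered list of steps (infuse, withdraw, extract,
wait, await-event, notify) executed against the pump network with chamber
volume bookkeeping, a complete execution log, and notification hooks.

Chamber mixing is modeled as perfect instantaneous mixing with a residual
floor (default 10% of working volume): extraction removes fluid from all
reagents proportionally and can never drain below the floor. This is a
modeling assumption; real open-chamber exchange dynamics are richer.

Incubation semantics: a reagent phase maps to INFUSE followed by WAIT; a
wash maps to INFUSE + EXTRACT (+ WAIT). Failure policy is halt-and-notify:
a hardware error mid-step logs the failure, marks the remaining steps
skipped and stops — sample integrity over throughput.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional

import yaml

from .clock import SimulatedClock
from .errors import (
    FluidloopError,
    InvalidArgumentError,
    ValidationError,
)
from .kinematics import flow_rate_to_step_period, volume_to_steps
from .network import DEFAULT_EXTRACTION_RATE, CommandFrame, SimulatedBus, Verb

DEFAULT_RESIDUAL_FRACTION = 0.10
DEFAULT_POST_TRIGGER_DELAY = 15.0  # minutes


class StepKind(str, enum.Enum):
    INFUSE = "INFUSE"
    WITHDRAW = "WITHDRAW"
    EXTRACT = "EXTRACT"
    WAIT = "WAIT"
    AWAIT_EVENT = "AWAIT_EVENT"
    NOTIFY = "NOTIFY"


MOTION_KINDS = {StepKind.INFUSE, StepKind.WITHDRAW, StepKind.EXTRACT}


@dataclass(frozen=True)
class ProtocolStep:
    """One protocol step. Motion kinds require pump, volume and rate;
    WAIT requires a positive duration; NOTIFY carries a message."""

    kind: StepKind
    pump: Optional[int] = None
    reagent: str = ""
    volume: Optional[float] = None       # uL
    rate: Optional[float] = None         # uL/min
    duration: Optional[float] = None     # minutes (WAIT)
    repeat: int = 1
    message: str = ""
    post_trigger_delay: float = DEFAULT_POST_TRIGGER_DELAY  # AWAIT_EVENT only

    def __post_init__(self) -> None:
        if self.repeat < 1:
            raise InvalidArgumentError(f"repeat must be >= 1, got {self.repeat}")
        if self.kind in (StepKind.INFUSE, StepKind.WITHDRAW):
            if self.pump is None or self.volume is None or self.rate is None:
                raise InvalidArgumentError(
                    f"{self.kind.value} step requires pump, volume and rate"
                )
            if self.volume < 0 or self.rate <= 0:
                raise InvalidArgumentError("volume must be >= 0 and rate > 0")
        elif self.kind is StepKind.EXTRACT:
            if self.volume is None or self.volume < 0:
                raise InvalidArgumentError("EXTRACT step requires volume >= 0")
        elif self.kind is StepKind.WAIT:
            if self.duration is None or self.duration <= 0:
                raise InvalidArgumentError("WAIT step requires duration > 0")
        elif self.kind is StepKind.AWAIT_EVENT:
            if self.post_trigger_delay < 0:
                raise InvalidArgumentError("post_trigger_delay must be >= 0")


class ChamberModel:
    """Open imaging chamber with per-reagent volume bookkeeping."""

    def __init__(
        self,
        working_volume: float = 1000.0,
        tubing_dead_volume: float = 50.0,
        residual_fraction: float = DEFAULT_RESIDUAL_FRACTION,
    ) -> None:
        if working_volume <= 0 or tubing_dead_volume < 0:
            raise InvalidArgumentError("chamber volumes must be positive")
        self.working_volume = working_volume
        self.tubing_dead_volume = tubing_dead_volume
        self.residual_floor = residual_fraction * working_volume
        self.contents: dict[str, float] = {}
        self.infused: dict[str, float] = {}
        self.extracted: dict[str, float] = {}

    @property
    def total_volume(self) -> float:
        return sum(self.contents.values())

    def add(self, reagent: str, volume: float) -> None:
        if volume < 0:
            raise InvalidArgumentError(f"cannot add negative volume {volume}")
        self.contents[reagent] = self.contents.get(reagent, 0.0) + volume
        self.infused[reagent] = self.infused.get(reagent, 0.0) + volume

    def extract(self, volume: float) -> float:
        """Remove up to ``volume`` uL proportionally across all reagents,
        never draining below the residual floor. Returns the volume removed."""
        if volume < 0:
            raise InvalidArgumentError(f"cannot extract negative volume {volume}")
        total = self.total_volume
        removable = max(total - self.residual_floor, 0.0)
        removed = min(volume, removable)
        if removed > 0 and total > 0:
            frac = removed / total
            for reagent in self.contents:
                taken = self.contents[reagent] * frac
                self.contents[reagent] -= taken
                self.extracted[reagent] = self.extracted.get(reagent, 0.0) + taken
        return removed


@dataclass
class Protocol:
    name: str
    steps: list[ProtocolStep]
    chamber: ChamberModel = field(default_factory=ChamberModel)
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self.steps:
            raise InvalidArgumentError("a protocol must contain at least one step")


@dataclass(frozen=True)
class LogEntry:
    timestamp: float  # simulated minutes
    step_index: int
    action: str
    pump: Optional[int]
    volume: Optional[float]
    outcome: str  # start | done | failed | skipped | fired | sent


class ExecutionLog:
    """Append-only, time-ordered record of an execution."""

    def __init__(self) -> None:
        self.entries: list[LogEntry] = []

    def append(self, entry: LogEntry) -> None:
        if self.entries and entry.timestamp < self.entries[-1].timestamp:
            raise InvalidArgumentError("log timestamps must be non-decreasing")
        self.entries.append(entry)

    def last_timestamp(self) -> float:
        return self.entries[-1].timestamp if self.entries else 0.0

    def to_rows(self) -> list[dict]:
        return [
            {
                "timestamp_min": e.timestamp,
                "step": e.step_index,
                "action": e.action,
                "pump": "" if e.pump is None else e.pump,
                "volume_ul": "" if e.volume is None else e.volume,
                "outcome": e.outcome,
            }
            for e in self.entries
        ]

    def write_csv(self, path) -> None:
        import csv

        rows = self.to_rows()
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["timestamp_min", "step", "action", "pump", "volume_ul", "outcome"],
            )
            writer.writeheader()
            writer.writerows(rows)


class EventSource:
    """Shared trigger between the orchestrator and AWAIT_EVENT steps.

    ``fire(t)`` records the simulated time the experiment-level event
    occurred; an AWAIT_EVENT step then resumes at ``t + post_trigger_delay``.
    """

    def __init__(self) -> None:
        self.fired_at: Optional[float] = None

    @property
    def fired(self) -> bool:
        return self.fired_at is not None

    def fire(self, t: float) -> None:
        if self.fired_at is None:  # single-firing: later calls are no-ops
            self.fired_at = t


@dataclass
class Hooks:
    """Pluggable callbacks; every hook is optional and never raises into
    the control loop."""

    notify: Optional[Callable[[str, float], None]] = None
    on_failure: Optional[Callable[[str, float], None]] = None
    event_source: Optional[EventSource] = None

    def send_notification(self, message: str, t: float, records: list) -> None:
        records.append((t, message))
        if self.notify is not None:
            try:
                self.notify(message, t)
            except Exception:  # noqa: BLE001 - hook failures must not halt runs
                pass

    def send_failure(self, message: str, t: float, records: list) -> None:
        records.append((t, f"FAILURE: {message}"))
        if self.on_failure is not None:
            try:
                self.on_failure(message, t)
            except Exception:  # noqa: BLE001
                pass


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate(protocol: Protocol, bus: Optional[SimulatedBus] = None) -> list[str]:
    """Static checks; returns findings (empty iff executable).

    Checks pump existence (when a bus is given), per-stroke volume vs.
    syringe capacity, and chamber overfill under the bookkeeping model.
    """
    findings: list[str] = []
    chamber_total = protocol.chamber.total_volume
    for i, step in enumerate(protocol.steps):
        if step.kind in (StepKind.INFUSE, StepKind.WITHDRAW):
            pump = None
            if bus is not None:
                pump = bus.pumps.get(step.pump)
                if pump is None:
                    findings.append(f"step {i}: unknown pump {step.pump}")
                    continue
            if pump is not None and step.volume > pump.syringe.capacity:
                findings.append(
                    f"step {i}: volume {step.volume} uL exceeds syringe "
                    f"capacity {pump.syringe.capacity} uL (no refill policy)"
                )
            if step.kind is StepKind.INFUSE:
                chamber_total += step.volume * step.repeat
                if chamber_total > protocol.chamber.working_volume and not _extract_follows(
                    protocol.steps, i
                ):
                    findings.append(
                        f"step {i}: chamber overfill ({chamber_total:.0f} uL > "
                        f"working volume {protocol.chamber.working_volume:.0f} uL) "
                        "with no extraction scheduled"
                    )
        elif step.kind is StepKind.EXTRACT:
            chamber_total = max(
                chamber_total - step.volume * step.repeat,
                protocol.chamber.residual_floor,
            )
    protocol._validated = not findings
    return findings


def _extract_follows(steps: list[ProtocolStep], index: int) -> bool:
    return any(s.kind is StepKind.EXTRACT for s in steps[index:])


def total_duration(protocol: Protocol) -> float:
    """Planned duration in minutes: motion time (volume/rate) plus WAIT
    durations, times repeats. AWAIT_EVENT is unbounded and contributes 0."""
    if not protocol._validated:
        raise ValidationError("protocol must pass validate() before planning")
    total = 0.0
    for step in protocol.steps:
        per = 0.0
        if step.kind in (StepKind.INFUSE, StepKind.WITHDRAW):
            per = step.volume / step.rate
        elif step.kind is StepKind.EXTRACT:
            per = step.volume / (step.rate or DEFAULT_EXTRACTION_RATE)
        elif step.kind is StepKind.WAIT:
            per = step.duration
        total += per * step.repeat
    return total


def wait_duration(protocol: Protocol) -> float:
    """Sum of WAIT durations only (the printed incubation times), minutes."""
    return sum(
        s.duration * s.repeat for s in protocol.steps if s.kind is StepKind.WAIT
    )


def overflow_dispense(loaded_aliquot: float, flush_volume: float, chamber: ChamberModel) -> float:
    """Delivered reagent volume under overflow loading (plug flow).

    A small aliquot pre-loaded in the tubing is pushed through by a larger
    carrier volume; once the flush exceeds the aliquot plus the tubing dead
    volume, the entire aliquot is guaranteed delivered.
    """
    if loaded_aliquot < 0 or flush_volume < 0:
        raise InvalidArgumentError("volumes must be >= 0")
    return min(loaded_aliquot, flush_volume)


def execute(
    protocol: Protocol,
    bus: SimulatedBus,
    clock: Optional[SimulatedClock] = None,
    hooks: Optional[Hooks] = None,
) -> ExecutionLog:
    """Run a validated protocol to completion (or first failure)."""
    if not protocol._validated:
        findings = validate(protocol, bus)
        if findings:
            raise ValidationError("; ".join(findings))
    clock = clock or bus.clock
    hooks = hooks or Hooks()
    log = ExecutionLog()
    notifications: list[tuple[float, str]] = []
    bus.bind_chamber(protocol.chamber)

    failed = False
    for i, step in enumerate(protocol.steps):
        if failed:
            log.append(LogEntry(clock.now, i, step.kind.value, step.pump, step.volume, "skipped"))
            continue
        for rep in range(step.repeat):
            try:
                _run_step(step, i, protocol, bus, clock, hooks, log, notifications)
            except FluidloopError as exc:
                log.append(
                    LogEntry(clock.now, i, step.kind.value, step.pump, step.volume, "failed")
                )
                hooks.send_failure(f"step {i} ({step.kind.value}): {exc}", clock.now, notifications)
                failed = True
                break

    log.notifications = notifications  # type: ignore[attr-defined]
    log.failed = failed  # type: ignore[attr-defined]
    return log


def _run_step(step, i, protocol, bus, clock, hooks, log, notifications) -> None:
    chamber = protocol.chamber
    if step.kind is StepKind.WAIT:
        log.append(LogEntry(clock.now, i, "WAIT", None, None, "start"))
        clock.advance(step.duration)
        bus.sync()
        log.append(LogEntry(clock.now, i, "WAIT", None, None, "done"))
    elif step.kind in (StepKind.INFUSE, StepKind.WITHDRAW):
        pump = bus.pumps[step.pump]
        steps_n = volume_to_steps(step.volume, pump.syringe, pump.config)
        period = flow_rate_to_step_period(step.rate, pump.syringe, pump.config)
        verb = Verb.INFUSE if step.kind is StepKind.INFUSE else Verb.WITHDRAW
        log.append(LogEntry(clock.now, i, step.kind.value, step.pump, step.volume, "start"))
        bus.dispatch(
            CommandFrame(verb=verb, address=step.pump, steps=steps_n, step_period=period)
        )
        clock.advance(step.volume / step.rate)
        bus.sync()
        bus.status(step.pump)  # settle the completed move
        if step.kind is StepKind.INFUSE:
            chamber.add(step.reagent or f"pump{step.pump}", step.volume)
            # Overfill beyond working volume spills into extraction when the
            # peristaltic pump is running; validation flags it otherwise.
            if chamber.total_volume > chamber.working_volume and bus.extraction_on:
                chamber.extract(chamber.total_volume - chamber.working_volume)
        log.append(LogEntry(clock.now, i, step.kind.value, step.pump, step.volume, "done"))
    elif step.kind is StepKind.EXTRACT:
        log.append(LogEntry(clock.now, i, "EXTRACT", None, step.volume, "start"))
        bus.dispatch(CommandFrame(verb=Verb.EXTRACT_ON, address=0))
        duration = step.volume / (step.rate or bus.extraction_rate)
        clock.advance(duration)
        bus.sync()
        bus.dispatch(CommandFrame(verb=Verb.EXTRACT_OFF, address=0))
        log.append(LogEntry(clock.now, i, "EXTRACT", None, step.volume, "done"))
    elif step.kind is StepKind.AWAIT_EVENT:
        log.append(LogEntry(clock.now, i, "AWAIT_EVENT", None, None, "start"))
        source = hooks.event_source
        if source is None or not source.fired:
            raise ValidationError(
                "AWAIT_EVENT step requires a fired event source "
                "(run through the orchestrator or fire it manually)"
            )
        clock.advance_to(source.fired_at + step.post_trigger_delay)
        bus.sync()
        log.append(LogEntry(clock.now, i, "AWAIT_EVENT", None, None, "fired"))
    elif step.kind is StepKind.NOTIFY:
        hooks.send_notification(step.message, clock.now, notifications)
        log.append(LogEntry(clock.now, i, "NOTIFY", None, None, "sent"))


# ---------------------------------------------------------------------------
# The published fixation/staining sequence and YAML (de)serialization
# ---------------------------------------------------------------------------

def mitotic_fixation_protocol(
    pumps: Optional[dict[str, int]] = None,
    volume: float = 500.0,
    rate: float = 10_000.0,
    chamber: Optional[ChamberModel] = None,
) -> Protocol:
    """Five-phase in-situ fixation and staining sequence.

    Phases (incubation times sum to 155 min): fixative 15 min; wash x3,
    10 min each; permeabilisation/blocking 30 min; stain 60 min; wash x2,
    10 min each. Reagent phases map to INFUSE+WAIT; washes add an EXTRACT
    of the infused volume. At the default high flow rate motion time is
    negligible next to the incubations.
    """
    pumps = pumps or {"fixative": 0, "pbs": 1, "block": 2, "stain": 3}
    chamber = chamber or ChamberModel(working_volume=2.5 * volume)
    steps: list[ProtocolStep] = []

    def phase(reagent: str, pump: int, minutes: float, repeat: int = 1) -> None:
        for _ in range(repeat):
            steps.append(
                ProtocolStep(
                    kind=StepKind.INFUSE, pump=pump, reagent=reagent, volume=volume, rate=rate
                )
            )
            steps.append(ProtocolStep(kind=StepKind.EXTRACT, volume=volume))
            steps.append(ProtocolStep(kind=StepKind.WAIT, duration=minutes))

    phase("fixative", pumps["fixative"], 15.0)
    phase("pbs-wash", pumps["pbs"], 10.0, repeat=3)
    phase("perm-block", pumps["block"], 30.0)
    phase("stain", pumps["stain"], 60.0)
    phase("pbs-wash", pumps["pbs"], 10.0, repeat=2)
    steps.append(ProtocolStep(kind=StepKind.NOTIFY, message="protocol complete"))
    return Protocol(name="fixation-staining", steps=steps, chamber=chamber)


def protocol_to_dict(protocol: Protocol) -> dict:
    steps = []
    for s in protocol.steps:
        d = {"kind": s.kind.value}
        for k in ("pump", "reagent", "volume", "rate", "duration", "message"):
            v = getattr(s, k)
            if v not in (None, ""):
                d[k] = v
        if s.repeat != 1:
            d["repeat"] = s.repeat
        if s.kind is StepKind.AWAIT_EVENT:
            d["post_trigger_delay"] = s.post_trigger_delay
        steps.append(d)
    return {
        "version": 1,
        "name": protocol.name,
        "chamber": {
            "working_volume": protocol.chamber.working_volume,
            "tubing_dead_volume": protocol.chamber.tubing_dead_volume,
        },
        "steps": steps,
    }


def protocol_from_dict(doc: dict) -> Protocol:
    if doc.get("version") != 1:
        raise InvalidArgumentError(f"unsupported protocol schema version {doc.get('version')}")
    ch = doc.get("chamber", {})
    chamber = ChamberModel(
        working_volume=ch.get("working_volume", 1000.0),
        tubing_dead_volume=ch.get("tubing_dead_volume", 50.0),
    )
    steps = []
    for d in doc["steps"]:
        kwargs = {k: d[k] for k in d if k != "kind"}
        steps.append(ProtocolStep(kind=StepKind(d["kind"]), **kwargs))
    return Protocol(name=doc.get("name", "protocol"), steps=steps, chamber=chamber)


def load_protocol(path) -> Protocol:
    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh))


def save_protocol(protocol: Protocol, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)
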