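"""Command/acknowledge protocol between a controller and a pump array.

A flat bus addresses up to 128 syringe pumps (addresses 0..127) plus one
peristaltic extraction pump. Frames are length-prefixed ASCII lines so a
serial transcript stays human-readable; the default backend is a fully
in-memory simulator driven by an injected :class:`~fluidloop.clock.SimulatedClock`.

The simulator enforces the single-controller contract: at most one motion
command may be active per pump, a second one is rejected as busy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .clock import MS_PER_MINUTE, SimulatedClock
from .errors import (
    AddressConflictError,
    AddressOutOfRangeError,
    BusError,
    InvalidArgumentError,
    NoAcknowledgeError,
    ProtocolFrameError,
    PumpBusyError,
)
from .kinematics import PumpConfig, SyringeSpec, steps_to_volume

MAX_PUMPS = 128
BROADCAST = None
#: Peristaltic extraction rate, uL/min. High (10 mL/min) so an exchange's
#: extraction time is negligible next to incubation times.
DEFAULT_EXTRACTION_RATE = 10_000.0


@dataclass(frozen=True)
class PumpAddress:
    """Bus address of one pump unit, in [0, 127]."""

    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < MAX_PUMPS:
            raise AddressOutOfRangeError(
                f"pump address must be in [0, {MAX_PUMPS - 1}], got {self.value}"
            )


class Verb(str, enum.Enum):
    INFUSE = "INFUSE"
    WITHDRAW = "WITHDRAW"
    STOP = "STOP"
    STATUS = "STATUS"
    EXTRACT_ON = "EXTRACT_ON"
    EXTRACT_OFF = "EXTRACT_OFF"


MOTION_VERBS = {Verb.INFUSE, Verb.WITHDRAW}


class PumpState(str, enum.Enum):
    IDLE = "IDLE"
    MOVING = "MOVING"
    ERROR = "ERROR"


@dataclass(frozen=True)
class CommandFrame:
    """One controller-to-pump command.

    ``address`` is an int in [0, 127] or ``None`` for broadcast.
    """

    verb: Verb
    address: Optional[int] = None
    steps: int = 0
    step_period: float = 0.0  # ms per step, motion verbs only
    sequence_id: int = 0

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ProtocolFrameError(f"steps must be >= 0, got {self.steps}")
        if self.verb in MOTION_VERBS and self.step_period <= 0:
            raise ProtocolFrameError(
                f"{self.verb.value} requires step_period > 0, got {self.step_period}"
            )
        if self.address is not None:
            PumpAddress(self.address)  # range check


@dataclass(frozen=True)
class StatusFrame:
    """Pump-to-controller acknowledge."""

    address: int
    state: PumpState
    steps_remaining: int = 0
    error_code: int = 0

    def __post_init__(self) -> None:
        if self.state is PumpState.IDLE and self.steps_remaining != 0:
            raise ProtocolFrameError("IDLE status must report steps_remaining == 0")


# ---------------------------------------------------------------------------
# ASCII wire framing (length-prefixed lines), shared by all transports
# ---------------------------------------------------------------------------

def encode_frame(frame: CommandFrame) -> str:
    addr = "*" if frame.address is None else str(frame.address)
    body = (
        f"{addr} {frame.verb.value} {frame.steps} "
        f"{frame.step_period:g} {frame.sequence_id}"
    )
    return f"{len(body):03d}|{body}\n"


def decode_frame(line: str) -> CommandFrame:
    line = line.rstrip("\n")
    try:
        prefix, body = line.split("|", 1)
        if int(prefix) != len(body):
            raise ProtocolFrameError(
                f"length prefix {prefix} does not match body length {len(body)}"
            )
        addr_s, verb_s, steps_s, period_s, seq_s = body.split()
        address = None if addr_s == "*" else int(addr_s)
        return CommandFrame(
            verb=Verb(verb_s),
            address=address,
            steps=int(steps_s),
            step_period=float(period_s),
            sequence_id=int(seq_s),
        )
    except ProtocolFrameError:
        raise
    except (ValueError, KeyError) as exc:
        raise ProtocolFrameError(f"malformed frame {line!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Simulated bus
# ---------------------------------------------------------------------------

@dataclass
class _SimPump:
    syringe: SyringeSpec
    config: PumpConfig
    state: PumpState = PumpState.IDLE
    motion_verb: Optional[Verb] = None
    motion_start: float = 0.0       # minutes
    motion_steps: int = 0
    step_period: float = 0.0        # ms
    steps_done_total: int = 0

    def motion_duration(self) -> float:
        """Total duration of the current move, minutes."""
        return self.motion_steps * self.step_period / MS_PER_MINUTE

    def steps_done(self, now: float) -> int:
        if self.state is not PumpState.MOVING:
            return 0
        elapsed_ms = (now - self.motion_start) * MS_PER_MINUTE
        done = int(elapsed_ms // self.step_period)
        return min(done, self.motion_steps)


class SimulatedBus:
    """In-memory pump array with a simulated clock.

    Motion consumes simulated time only: a pump commanded N steps at
    ``step_period`` ms finishes when the injected clock has advanced past
    ``N * step_period``. Status polls are side-effect-free apart from
    settling completed moves.
    """

    def __init__(
        self,
        clock: Optional[SimulatedClock] = None,
        extraction_rate: float = DEFAULT_EXTRACTION_RATE,
    ) -> None:
        self.clock = clock or SimulatedClock()
        self.pumps: dict[int, _SimPump] = {}
        self.extraction_attached: bool = True
        self.extraction_rate = extraction_rate  # uL/min
        self._extraction_on = False
        self._extraction_since: Optional[float] = None
        self.chamber = None  # bound by the protocol engine
        self.transcript: list[tuple[float, str, str]] = []
        self._fail_next: int = 0

    # -- wiring ------------------------------------------------------------

    def attach_pump(self, address: int, syringe: SyringeSpec, config: PumpConfig) -> None:
        if not 0 <= address < MAX_PUMPS:
            raise AddressOutOfRangeError(
                f"address {address} outside the {MAX_PUMPS}-unit bus"
            )
        if address in self.pumps:
            raise AddressConflictError(f"pump already attached at address {address}")
        self.pumps[address] = _SimPump(syringe=syringe, config=config)

    def detach_pump(self, address: int) -> None:
        self.pumps.pop(address, None)

    def bind_chamber(self, chamber) -> None:
        """Attach the chamber model drained by the extraction pump."""
        self.chamber = chamber

    def inject_fault(self, n: int = 1) -> None:
        """Make the next ``n`` dispatches fail with a bus error (tests)."""
        self._fail_next += n

    # -- extraction bookkeeping -------------------------------------------

    @property
    def extraction_on(self) -> bool:
        return self._extraction_on

    def sync(self) -> None:
        """Integrate extraction-pump withdrawal up to the current time."""
        if self._extraction_on and self.chamber is not None:
            dt = self.clock.now - self._extraction_since
            if dt > 0:
                self.chamber.extract(self.extraction_rate * dt)
        if self._extraction_on:
            self._extraction_since = self.clock.now

    # -- protocol ----------------------------------------------------------

    def dispatch(self, frame: CommandFrame) -> StatusFrame:
        self.transcript.append((self.clock.now, "tx", encode_frame(frame).strip()))
        if self._fail_next > 0:
            self._fail_next -= 1
            raise BusError("simulated transport fault")
        if frame.address is None:
            if frame.verb is not Verb.STOP:
                raise ProtocolFrameError("broadcast supports STOP only")
            for addr in sorted(self.pumps):
                self._dispatch_one(CommandFrame(verb=Verb.STOP, address=addr))
            status = StatusFrame(address=0, state=PumpState.IDLE)
        else:
            status = self._dispatch_one(frame)
        self.transcript.append(
            (self.clock.now, "rx", f"{status.address} {status.state.value} {status.steps_remaining}")
        )
        return status

    def _dispatch_one(self, frame: CommandFrame) -> StatusFrame:
        if frame.verb in (Verb.EXTRACT_ON, Verb.EXTRACT_OFF):
            return self._dispatch_extraction(frame)
        pump = self.pumps.get(frame.address)
        if pump is None:
            raise NoAcknowledgeError(f"no pump at address {frame.address}")
        self._settle(frame.address, pump)
        if frame.verb in MOTION_VERBS:
            if pump.state is PumpState.MOVING:
                raise PumpBusyError(
                    f"pump {frame.address} is moving; motion command rejected"
                )
            pump.state = PumpState.MOVING
            pump.motion_verb = frame.verb
            pump.motion_start = self.clock.now
            pump.motion_steps = frame.steps
            pump.step_period = frame.step_period
            return StatusFrame(
                address=frame.address, state=PumpState.MOVING, steps_remaining=frame.steps
            )
        if frame.verb is Verb.STOP:
            if pump.state is PumpState.MOVING:
                pump.steps_done_total += pump.steps_done(self.clock.now)
            pump.state = PumpState.IDLE
            pump.motion_steps = 0
            return StatusFrame(address=frame.address, state=PumpState.IDLE)
        if frame.verb is Verb.STATUS:
            remaining = (
                pump.motion_steps - pump.steps_done(self.clock.now)
                if pump.state is PumpState.MOVING
                else 0
            )
            return StatusFrame(
                address=frame.address, state=pump.state, steps_remaining=remaining
            )
        raise ProtocolFrameError(f"unsupported verb {frame.verb}")  # pragma: no cover

    def _dispatch_extraction(self, frame: CommandFrame) -> StatusFrame:
        if not self.extraction_attached:
            raise NoAcknowledgeError("no peristaltic extraction unit attached")
        self.sync()
        want_on = frame.verb is Verb.EXTRACT_ON
        if want_on and not self._extraction_on:
            self._extraction_on = True
            self._extraction_since = self.clock.now
        elif not want_on and self._extraction_on:
            self._extraction_on = False
            self._extraction_since = None
        state = PumpState.MOVING if self._extraction_on else PumpState.IDLE
        return StatusFrame(address=frame.address or 0, state=state)

    def _settle(self, address: int, pump: _SimPump) -> None:
        """Mark a move complete once simulated time has passed its end."""
        if pump.state is PumpState.MOVING:
            if self.clock.now >= pump.motion_start + pump.motion_duration():
                pump.steps_done_total += pump.motion_steps
                pump.state = PumpState.IDLE
                pump.motion_steps = 0

    # -- queries -----------------------------------------------------------

    def status(self, address: int) -> StatusFrame:
        return self.dispatch(CommandFrame(verb=Verb.STATUS, address=address))

    def dispensed_volume(self, address: int) -> float:
        """Total volume moved by a pump so far (partial moves included), uL."""
        pump = self.pumps.get(address)
        if pump is None:
            raise NoAcknowledgeError(f"no pump at address {address}")
        steps = pump.steps_done_total
        if pump.state is PumpState.MOVING:
            steps += pump.steps_done(self.clock.now)
        return steps_to_volume(steps, pump.syringe, pump.config)


def enumerate_pumps(bus: SimulatedBus) -> list[int]:
    """Probe every address with STATUS; return acknowledging addresses sorted."""
    found = []
    for addr in range(MAX_PUMPS):
        try:
            bus.status(addr)
        except NoAcknowledgeError:
            continue
        found.append(addr)
    return found


def attach_pump(bus: SimulatedBus, address: int, syringe: SyringeSpec, config: PumpConfig) -> None:
    bus.attach_pump(address, syringe, config)


def dispatch(bus: SimulatedBus, frame: CommandFrame) -> StatusFrame:
    return bus.dispatch(frame)


def extraction_pump(bus: SimulatedBus, on: bool) -> StatusFrame:
    verb = Verb.EXTRACT_ON if on else Verb.EXTRACT_OFF
    return bus.dispatch(CommandFrame(verb=verb, address=0))
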