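"""The closed live-to-fixed acquisition loop.

Phases advance monotonically LIVE -> TRIGGERED_WAIT -> FLUIDICS ->
POSTFIX -> DONE (FAILED is reachable from anywhere): frames are acquired
per FOV on a fixed cadence and fed to the rounding detector; when the
experiment-level event fires, a configurable delay elapses (live imaging
continues through it), the fluid-exchange protocol runs, and the post-fix
z-stack acquisition plan is logged. Notification hooks fire at every
stage transition and never raise into the loop.

Exactly one event fires per run — automatic or manual, whichever first.
Activation time equals event time plus the post-trigger delay, exactly,
on the simulated clock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import tifffile

from .clock import SimulatedClock
from .detection import TriggerConfig, TriggerTracker
from .errors import InvalidArgumentError, InvalidStateError
from .network import SimulatedBus
from .protocol import (
    EventSource,
    ExecutionLog,
    Hooks,
    LogEntry,
    Protocol,
    execute,
    validate,
)
from .synth import FOVScenario, render_frame


@dataclass(frozen=True)
class AcquisitionPlan:
    """Live cadence plus the post-fixation z-stack description."""

    n_fov: int = 45
    frame_interval: float = 5.0                  # minutes
    duration: float = 60.0                       # minutes of live imaging max
    live_channels: tuple[str, ...] = ("GFP",)
    postfix_planes: int = 35
    postfix_spacing_um: float = 0.5
    postfix_channels: tuple[str, ...] = ("DAPI", "GFP", "mCherry", "AF647")

    def __post_init__(self) -> None:
        if self.n_fov < 1:
            raise InvalidArgumentError("n_fov must be >= 1")
        if self.frame_interval <= 0 or self.postfix_spacing_um <= 0:
            raise InvalidArgumentError("frame_interval and z spacing must be > 0")


class Phase(str, enum.Enum):
    LIVE = "LIVE"
    TRIGGERED_WAIT = "TRIGGERED_WAIT"
    FLUIDICS = "FLUIDICS"
    POSTFIX = "POSTFIX"
    DONE = "DONE"
    FAILED = "FAILED"


_ORDER = [Phase.LIVE, Phase.TRIGGERED_WAIT, Phase.FLUIDICS, Phase.POSTFIX, Phase.DONE]


@dataclass
class RunState:
    phase: Phase = Phase.LIVE
    event_time: Optional[float] = None
    activation_time: Optional[float] = None
    manual: bool = False
    notifications: list[tuple[float, str]] = field(default_factory=list)

    def advance(self, phase: Phase) -> None:
        if phase is Phase.FAILED:
            self.phase = phase
            return
        if _ORDER.index(phase) < _ORDER.index(self.phase):
            raise InvalidStateError(f"cannot move from {self.phase} back to {phase}")
        self.phase = phase


class ImageSource:
    """Frame iterator contract: one frame per FOV per cadence tick."""

    fov_ids: tuple[int, ...]

    def frame(self, fov_id: int, t: float) -> np.ndarray:
        raise NotImplementedError


class SyntheticImageSource(ImageSource):
    """Renders frames on demand from per-FOV scenarios."""

    def __init__(self, scenarios: Iterable[FOVScenario]) -> None:
        self.scenarios = {sc.fov_id: sc for sc in scenarios}
        self.fov_ids = tuple(sorted(self.scenarios))

    def frame(self, fov_id: int, t: float) -> np.ndarray:
        return render_frame(self.scenarios[fov_id], t)


class TiffReplaySource(ImageSource):
    """Replays recorded per-FOV TIFF stacks written by
    :func:`fluidloop.synth.generate_experiment`."""

    def __init__(self, directory, frame_interval: float = 5.0) -> None:
        directory = Path(directory)
        self.stacks: dict[int, np.ndarray] = {}
        for path in sorted(directory.glob("fov_*.tif")):
            fov_id = int(path.stem.split("_")[1])
            self.stacks[fov_id] = tifffile.imread(path)
        if not self.stacks:
            raise InvalidArgumentError(f"no fov_*.tif stacks found in {directory}")
        self.fov_ids = tuple(sorted(self.stacks))
        self.frame_interval = frame_interval

    def frame(self, fov_id: int, t: float) -> np.ndarray:
        index = int(round(t / self.frame_interval))
        stack = self.stacks[fov_id]
        if not 0 <= index < len(stack):
            raise InvalidArgumentError(f"no recorded frame at t={t} for FOV {fov_id}")
        return stack[index]


class ExperimentRun:
    """One orchestrated experiment; create, then call :meth:`run`."""

    def __init__(
        self,
        plan: AcquisitionPlan,
        trigger_cfg: TriggerConfig,
        protocol: Protocol,
        image_source: ImageSource,
        bus: SimulatedBus,
        clock: Optional[SimulatedClock] = None,
        hooks: Optional[Hooks] = None,
    ) -> None:
        self.plan = plan
        self.cfg = trigger_cfg
        self.protocol = protocol
        self.source = image_source
        self.bus = bus
        self.clock = clock or bus.clock
        self.event_source = EventSource()
        self.hooks = hooks or Hooks()
        self.hooks.event_source = self.event_source
        self.state = RunState()
        self.log = ExecutionLog()
        self.tracker = TriggerTracker(image_source.fov_ids, trigger_cfg)
        self._manual_requested: Optional[float] = None

    # -- public API --------------------------------------------------------

    def manual_trigger(self, at_time: Optional[float] = None) -> None:
        """Fire the event, as if the rounding cue had been observed by eye.

        Only valid while live imaging is running and before any automatic
        event. With no argument the event fires at the current simulated
        time; ``at_time`` fires it at that (current-or-future) time during
        :meth:`run` — use it to schedule a manual trigger before calling
        ``run``. The post-trigger delay still applies if configured > 0.
        """
        if self.state.phase is not Phase.LIVE or self.event_source.fired:
            raise InvalidStateError(
                f"manual trigger not allowed in phase {self.state.phase.value}"
                + (" (event already fired)" if self.event_source.fired else "")
            )
        if at_time is not None and at_time > self.clock.now:
            self._manual_requested = at_time
            return
        t = self.clock.now if at_time is None else at_time
        self.event_source.fire(t)
        self.state.manual = True
        self.state.event_time = t
        self._notify(f"manual trigger at t={t:g} min")

    def run(self) -> tuple[RunState, ExecutionLog]:
        findings = validate(self.protocol, self.bus)
        if findings:
            raise InvalidArgumentError("protocol invalid: " + "; ".join(findings))
        self._notify("live imaging started")
        try:
            self._live_loop()
            if self.event_source.fired:
                self._triggered_wait()
                self._fluidics()
                self._postfix()
            self.state.advance(Phase.DONE)
            if self.state.event_time is None:
                self._notify("live imaging exhausted without event")
            self._notify("run complete")
        except Exception as exc:  # halt-and-notify, never silent
            self.state.advance(Phase.FAILED)
            self.hooks.send_failure(str(exc), self.clock.now, self.state.notifications)
            self.log.append(
                LogEntry(self.clock.now, -1, "RUN", None, None, "failed")
            )
        return self.state, self.log

    # -- phases ------------------------------------------------------------

    def _acquire_all(self, t: float) -> None:
        for fov in self.source.fov_ids:
            self.tracker.update(fov, self.source.frame(fov, t), t)
        self.log.append(LogEntry(t, -1, "ACQUIRE_LIVE", None, None, "done"))

    def _live_loop(self) -> None:
        n_frames = int(round(self.plan.duration / self.plan.frame_interval)) + 1
        for i in range(n_frames):
            t = i * self.plan.frame_interval
            req = self._manual_requested
            if req is not None and req <= t and not self.event_source.fired:
                self._manual_requested = None
                self.clock.advance_to(req)
                self.manual_trigger(at_time=req)
                if t > req + self.cfg.post_trigger_delay:
                    break  # activation falls before this frame
            self.clock.advance_to(t)
            self._acquire_all(t)
            if not self.event_source.fired:
                fraction, fired, event_time = self.tracker.check()
                if fired:
                    self.event_source.fire(event_time)
                    self.state.event_time = event_time
                    self._notify(
                        f"rounding event fired at t={event_time:g} min "
                        f"({fraction:.1%} of FOVs triggered)"
                    )
            if self.event_source.fired:
                # Live imaging continues through the delay window; stop
                # once the next frame would land after pump activation.
                activation = self.event_source.fired_at + self.cfg.post_trigger_delay
                if t + self.plan.frame_interval > activation:
                    break

    def _triggered_wait(self) -> None:
        self.state.advance(Phase.TRIGGERED_WAIT)
        activation = self.event_source.fired_at + self.cfg.post_trigger_delay
        self.clock.advance_to(activation)
        self.state.activation_time = self.clock.now

    def _fluidics(self) -> None:
        self.state.advance(Phase.FLUIDICS)
        self._notify(f"fluidics protocol started at t={self.clock.now:g} min")
        self.log.append(
            LogEntry(self.clock.now, -1, "PUMP_ACTIVATION", None, None, "start")
        )
        inner = execute(self.protocol, self.bus, self.clock, self.hooks)
        for entry in inner.entries:
            self.log.append(entry)
        self.state.notifications.extend(getattr(inner, "notifications", []))
        if getattr(inner, "failed", False):
            raise InvalidStateError("fluidics protocol failed")
        self._notify("fluidics protocol complete")

    def _postfix(self) -> None:
        self.state.advance(Phase.POSTFIX)
        self._notify("post-fixation acquisition started")
        for fov in self.source.fov_ids:
            for channel in self.plan.postfix_channels:
                self.log.append(
                    LogEntry(
                        self.clock.now,
                        -1,
                        f"ACQUIRE_ZSTACK fov={fov} ch={channel} "
                        f"planes={self.plan.postfix_planes} "
                        f"dz={self.plan.postfix_spacing_um}um",
                        None,
                        None,
                        "done",
                    )
                )
        self._notify("post-fixation acquisition complete")

    def _notify(self, message: str) -> None:
        self.hooks.send_notification(message, self.clock.now, self.state.notifications)


def run(
    plan: AcquisitionPlan,
    trigger_cfg: TriggerConfig,
    protocol: Protocol,
    image_source: ImageSource,
    bus: SimulatedBus,
    clock: Optional[SimulatedClock] = None,
    hooks: Optional[Hooks] = None,
) -> tuple[RunState, ExecutionLog]:
    """Convenience wrapper: build an :class:`ExperimentRun` and run it."""
    return ExperimentRun(plan, trigger_cfg, protocol, image_source, bus, clock, hooks).run()


def pump_activation_time(log: ExecutionLog) -> Optional[float]:
    """Simulated time of the PUMP_ACTIVATION entry, if present."""
    for entry in log.entries:
        if entry.action == "PUMP_ACTIVATION":
            return entry.timestamp
    return None
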