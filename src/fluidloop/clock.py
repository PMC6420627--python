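"""Injected simulated clock.

Every time-dependent component in fluidloop receives a clock object instead
of reading wall time, so tests and acceptance runs never sleep. Time is kept
in simulated minutes (float); sub-second pump motion converts from ms.
"""

from __future__ import annotations

from .errors import InvalidArgumentError

MS_PER_MINUTE = 60_000.0


class SimulatedClock:
    """Monotonic simulated clock measured in minutes."""

    def __init__(self, start: float = 0.0) -> None:
        self._now = float(start)

    @property
    def now(self) -> float:
        """Current simulated time in minutes."""
        return self._now

    def advance(self, minutes: float) -> float:
        if minutes < 0:
            raise InvalidArgumentError(f"cannot advance clock by {minutes} min")
        self._now += minutes
        return self._now

    def advance_to(self, t: float) -> float:
        """Advance to absolute time ``t``; no-op if ``t`` is in the past."""
        if t > self._now:
            self._now = t
        return self._now

    def __repr__(self) -> str:  # pragma: no cover
        return f"SimulatedClock(t={self._now:.3f} min)"
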