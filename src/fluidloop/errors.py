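"""Exception hierarchy for fluidloop.

All library errors derive from :class:`FluidloopError` so callers can catch
one base class at CLI boundaries.
"""


class FluidloopError(Exception):
    """Base class for all fluidloop errors."""


class InvalidConfigurationError(FluidloopError):
    """Pump or syringe geometry is physically impossible."""


class InvalidArgumentError(FluidloopError, ValueError):
    """An operation received an out-of-domain argument."""


class CapacityExceededError(InvalidArgumentError):
    """Requested volume exceeds the syringe capacity."""


class AddressOutOfRangeError(InvalidArgumentError):
    """Pump address outside the 0..127 bus address space."""


class AddressConflictError(FluidloopError):
    """A pump is already attached at the requested address."""


class NoAcknowledgeError(FluidloopError):
    """No pump answered at the addressed bus position."""


class BusError(FluidloopError):
    """Transport-level failure on the pump bus."""


class ProtocolFrameError(BusError):
    """A command frame was malformed or could not be decoded."""


class PumpBusyError(FluidloopError):
    """A motion command was sent to a pump that is already moving."""


class ValidationError(FluidloopError):
    """A protocol failed validation and cannot be executed."""


class InvalidStateError(FluidloopError):
    """Operation not permitted in the current run phase."""


class InvalidGroupingError(InvalidArgumentError):
    """Calibration measurements grouped across mixed nominal volumes."""


class InsufficientReplicatesError(InvalidArgumentError):
    """Too few replicates for the requested statistic."""


class InvalidDesignError(InvalidArgumentError):
    """Calibration design is degenerate (e.g. a single nominal volume)."""
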