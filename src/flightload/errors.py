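"""Exception hierarchy for the flightload package."""


class FlightloadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlightloadError, ValueError):
    """A parameter object violates its invariants."""


class ValidationError(FlightloadError, ValueError):
    """An input record (log, rating sheet, table) is malformed."""


class InsufficientDataError(FlightloadError, ValueError):
    """Too little data to compute the requested quantity."""


class DataQualityError(FlightloadError, ValueError):
    """Data failed automated quality screening (e.g. too many RR artifacts)."""


class MetricError(FlightloadError, ValueError):
    """A performance metric is undefined for the given log."""


class StageError(FlightloadError, RuntimeError):
    """A study pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
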