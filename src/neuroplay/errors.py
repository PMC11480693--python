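"""Exception hierarchy."""


class NeuroplayError(Exception):
    """Base class for all package errors."""


class CalibrationError(NeuroplayError):
    """Raised when a calibration profile cannot be derived (e.g. a sensor's
    maximal-pressure window does not exceed its minimal-pressure window)."""


class SessionParseError(NeuroplayError):
    """Malformed session file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GameError(NeuroplayError):
    """Unknown game identifier or stream/program mismatch."""


class DegenerateInputError(NeuroplayError):
    """Statistical input with no usable variation (constant vector, single
    group, single-class labels)."""


class ConfigError(NeuroplayError):
    """Invalid generator or pipeline configuration."""
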