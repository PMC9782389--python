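"""Exception hierarchy for the error-decomposition pipeline."""


class ImusepError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ImusepError):
    """Non-finite or otherwise malformed numeric input."""


class EmptyInputError(ImusepError):
    """An operation received an empty series or group."""


class DegenerateFrameError(ImusepError):
    """Axes collinear / marker geometry degenerate — no frame can be built."""


class FrameMismatchError(ImusepError):
    """Two series disagree in length, timestamps or reference frame labels."""


class NotStaticError(ImusepError):
    """A window declared static contains motion above the guard threshold."""


class InsufficientExcitationError(ImusepError):
    """A functional-calibration or sync window lacks usable rotation."""


class GapError(ImusepError):
    """Marker trajectory contains NaN gaps; gap filling is out of scope."""


class InvalidCalibrationError(ImusepError):
    """Sensor-calibration parameters are unusable (e.g. singular alignment)."""


class InvalidConfigError(ImusepError):
    """Unknown movement label or inconsistent configuration values."""


class MissingFrameError(ImusepError):
    """A required frame series is absent for a requested comparison."""


class ParseError(ImusepError):
    """A CSV file violates the documented dialect."""
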