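"""Exception hierarchy shared across the package."""


class MTArrayError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MTArrayError, ValueError):
    """A generator or run configuration violates its invariants."""


class InvalidInputError(MTArrayError, ValueError):
    """An operation received input outside its domain."""


class EmptyInputError(InvalidInputError):
    """An operation that requires data received none."""


class DegenerateInputError(InvalidInputError):
    """Geometrically degenerate input (zero-length segment, flat profile...)."""


class AnnotationError(InvalidInputError):
    """Required annotation (polarity, seed anchor, censoring label) missing."""


class InsufficientDataError(InvalidInputError):
    """Fewer records than the operation needs (e.g. < 2 calibration points)."""


class AlignmentError(InvalidInputError):
    """Two series that must share a timebase do not."""
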