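"""Exception hierarchy shared by all modules."""


class SCPKaczmarzError(Exception):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(SCPKaczmarzError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ShapeError(SCPKaczmarzError, ValueError):
    """Array dimensions are mutually inconsistent."""


class DegenerateInputError(SCPKaczmarzError, ValueError):
    """Input is structurally degenerate (all-zero matrix, no usable rows, ...)."""


class LayoutError(SCPKaczmarzError, ValueError):
    """A source/detector position violates the imaging-geometry rules."""


class UndefinedMetricError(SCPKaczmarzError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero ground truth)."""


class ParseError(SCPKaczmarzError, ValueError):
    """A file could not be parsed; the message carries the offending location."""


class NumericalError(SCPKaczmarzError, RuntimeError):
    """A linear solve failed unexpectedly (singular discrete operator)."""
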