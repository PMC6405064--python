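"""Exception hierarchy."""


class CalciscanError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CalciscanError):
    """A required column is missing from an input table."""


class TableParseError(CalciscanError):
    """A cell could not be parsed; message names row and column."""


class ValidationError(CalciscanError):
    """A parsed value violates a domain invariant."""


class CalibrationError(CalciscanError):
    """Reference regions missing, degenerate, or too small."""


class SegmentationError(CalciscanError):
    """No shell component survives segmentation."""


class ResolutionError(CalciscanError):
    """Requested geometry is below the measurable resolution."""
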