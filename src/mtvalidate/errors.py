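"""Exception hierarchy for the mtvalidate pipeline.

Every stage raises a subclass of :class:`MTValidateError` so the pipeline
driver can halt with the stage name and offending file.
"""


class MTValidateError(Exception):
    """Base class for all mtvalidate errors."""


class ParameterError(MTValidateError, ValueError):
    """Invalid parameter value (non-positive rate, bad window, ...)."""


class ParseError(MTValidateError, ValueError):
    """A raw sensor log could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class FormatError(MTValidateError, ValueError):
    """A structured input file violates its dialect (markers, manifest)."""


class DataError(MTValidateError, ValueError):
    """Data content is unusable (gap too long, non-positive baseline, ...)."""


class GeometryError(MTValidateError, ValueError):
    """Marker geometry is degenerate (collinear, swapped, missing)."""


class SimulationError(MTValidateError, RuntimeError):
    """Inconsistent sensor-physics parameters produced impossible output."""


class AlignmentError(MTValidateError, ValueError):
    """Two streams share no overlapping time window."""


class ConfigurationError(MTValidateError, ValueError):
    """A run configuration or sensor map is invalid or incomplete."""
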