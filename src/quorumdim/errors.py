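"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`QuorumdimError`, so callers (and the
CLI driver) can catch pipeline failures without masking programming errors.
"""


class QuorumdimError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QuorumdimError):
    """An input table is missing a required (mapped) column."""


class EmptyInputError(QuorumdimError):
    """An input table or value collection contained no usable rows."""


class GridValidationError(QuorumdimError):
    """A concentration grid violates its invariants (unsorted/duplicate levels)."""


class DegenerateDataError(QuorumdimError):
    """Data too degenerate for the requested operation (e.g. ties collapse bins)."""


class InsufficientDataError(QuorumdimError):
    """Not enough observations/conditions to fit reliably."""


class ZeroVarianceError(QuorumdimError):
    """All points identical; a variance decomposition is undefined."""


class MissingNodeError(QuorumdimError):
    """A grid node lacks the value required for interpolation."""


class FlatSurfaceError(QuorumdimError):
    """The response coordinate is constant; a flat-output prior is undefined."""


class OutOfRangeError(QuorumdimError):
    """A reading lies outside the calibrated response range."""


class PipelineStageError(QuorumdimError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
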