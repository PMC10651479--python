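"""Exception hierarchy shared across the pipeline."""


class TissueDCError(Exception):
    """Base class for all package errors."""


class ParameterError(TissueDCError, ValueError):
    """Invalid user-supplied parameter (distribution spec, gate config, ...)."""


class GeometryError(TissueDCError, ValueError):
    """Degenerate or out-of-bounds geometry (zero-area contour, shape outside frame)."""


class SchemaError(TissueDCError, ValueError):
    """Event table is missing required columns or columns do not match."""


class FormatError(TissueDCError, IOError):
    """File is not a recognized event-container layout."""


class DegenerateInputError(TissueDCError, ValueError):
    """Statistical input with no usable variation (all-zero differences, zero variance)."""


class IncompleteBinError(TissueDCError, ValueError):
    """A size bin holds fewer events than required in strict mode."""
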