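"""Exception hierarchy shared across the package."""


class OncochromError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OncochromError):
    """Invalid configuration values (bad fractions, unknown modes, ...)."""


class ValidationError(OncochromError):
    """Invalid data handed to an operation."""


class DimensionError(ValidationError):
    """Tracks or vectors that should share a grid/length do not."""


class NormalizationError(OncochromError):
    """Scaling or input-normalization cannot proceed (e.g. zero totals)."""


class ParseError(ValidationError):
    """Malformed input file; carries path and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            if line is not None:
                ctx += f":{line}"
            ctx += "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class FitError(OncochromError):
    """Model fitting failed (rank deficiency, degenerate design)."""


class CalibrationError(OncochromError):
    """Ploidy calibration missing anchors or non-positive slope."""


class PlacementError(OncochromError):
    """Simulated features do not fit on the assembly."""


class StageError(OncochromError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
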