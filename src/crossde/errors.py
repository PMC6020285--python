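"""Exception hierarchy shared across the package."""


class CrossDEError(Exception):
    """Base class for all crossde errors."""


class ValidationError(CrossDEError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(CrossDEError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SchemaError(CrossDEError, ValueError):
    """A table is missing required columns."""


class StageError(CrossDEError, RuntimeError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
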