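"""Exception types shared across the package."""


class KrfbhoError(Exception):
    """Base class for all package errors."""


class ParseError(KrfbhoError, ValueError):
    """Malformed input file (ragged row, non-numeric field, missing header)."""


class ValidationError(KrfbhoError, ValueError):
    """Input violates a documented precondition."""


class ImputationError(KrfbhoError, ValueError):
    """Imputation impossible (e.g. no fully observed row exists)."""


class EncodingError(KrfbhoError, ValueError):
    """Presence/absence encoding applied to a column with >2 levels."""


class StageError(KrfbhoError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
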