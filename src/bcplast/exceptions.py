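"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`BcplastError`
so callers (and the CLI) can catch one base class.
"""


class BcplastError(Exception):
    """Base class for all package errors."""


class ParameterError(BcplastError, ValueError):
    """A function parameter is outside its documented domain."""


class DegenerateInputError(BcplastError, ValueError):
    """Input is structurally valid but statistically degenerate
    (single group, zero events, constant vector, ...)."""


class NoValidCutpointError(DegenerateInputError):
    """No candidate expression cutpoint exists inside the quantile band."""


class AlignmentError(BcplastError):
    """Sample identifiers of two inputs do not line up."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class MissingGenesError(BcplastError):
    """Requested signature genes are absent from the expression matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"{len(self.missing)} signature gene(s) missing from matrix: "
            + ", ".join(map(str, self.missing[:10]))
            + ("..." if len(self.missing) > 10 else "")
        )


class InsufficientOverlapError(BcplastError):
    """Too few signature genes overlap the sample to compute a correlation."""


class UndefinedCorrelationError(DegenerateInputError):
    """Correlation undefined (constant vector)."""


class PairingError(BcplastError):
    """Paired arms do not form a bijection."""


class LabelError(BcplastError):
    """A subtype label is not among the declared class names."""


class ValidationError(BcplastError):
    """A file failed format validation on read."""
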