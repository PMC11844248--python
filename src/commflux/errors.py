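"""Shared exception types."""


class CommfluxError(Exception):
    """Base class for package errors."""


class FormatError(CommfluxError):
    """A file could not be parsed in the declared format."""


class ValidationError(CommfluxError):
    """A model or data structure violates an invariant."""


class OptimizationError(CommfluxError):
    """An LP/QP stage failed (infeasible, unbounded, or solver failure)."""

    def __init__(self, message: str, status: str = "failed"):
        super().__init__(message)
        self.status = status
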