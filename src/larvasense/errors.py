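"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: user errors -> 1, numerical failures -> 2.
"""


class LarvasenseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidParameterError(LarvasenseError, ValueError):
    """A parameter violates its documented domain."""


class InsufficientDataError(LarvasenseError, ValueError):
    """The input is too short / too small for the requested operation."""


class FormatError(LarvasenseError, ValueError):
    """A file does not follow the expected on-disk dialect."""


class NumericalFailureError(LarvasenseError, RuntimeError):
    """An iterative numerical procedure failed to converge."""

    exit_code = 2

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
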