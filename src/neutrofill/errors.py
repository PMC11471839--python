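"""Exception hierarchy shared across the package."""


class NeutrofillError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NeutrofillError, ValueError):
    """A pixel intensity lies outside the configured pixel domain."""


class ConfigurationError(NeutrofillError, ValueError):
    """An invalid parameter or option combination was supplied."""


class ShapeError(NeutrofillError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class ValidationError(NeutrofillError, ValueError):
    """Input data violates a structural contract (e.g. non-binary mask)."""


class FormatError(NeutrofillError, ValueError):
    """A file could not be read or its format is unsupported."""


class PreconditionError(NeutrofillError, ValueError):
    """A documented precondition of an operation was violated."""


class TrainingDivergenceError(NeutrofillError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str = ""):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
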