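"""Exception hierarchy shared across the package."""


class MiBurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MiBurdenError, ValueError):
    """Invalid configuration (distributions not summing to one, bad hyperparameters, ...)."""


class FormatError(MiBurdenError, ValueError):
    """Malformed input file: missing column, non-numeric cell, duplicate key."""


class ValidationError(MiBurdenError, ValueError):
    """Structurally valid input violating a model precondition (negative rate, incomplete grid)."""


class SpecificationError(MiBurdenError, ValueError):
    """Model specification cannot be realised on the data (e.g. spline df exceeds support)."""


class DataError(MiBurdenError, ValueError):
    """Data violates a fitting precondition (e.g. negative cost outcomes)."""


class ModelError(MiBurdenError, RuntimeError):
    """Fit or prediction failure: non-convergence, non-positive predicted cost cell."""


class DomainError(MiBurdenError, ValueError):
    """Scalar argument outside its mathematical domain."""
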