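"""Exception hierarchy shared across the package."""


class PolarMaceError(Exception):
    """Base class for all package errors."""


class ValidationError(PolarMaceError, ValueError):
    """Data violates an invariant (non-finite, negative, wrong dtype...)."""


class ShapeError(ValidationError):
    """A measurement matrix has the wrong dimensions."""


class ConfigurationError(PolarMaceError, ValueError):
    """Inconsistent or out-of-range configuration values."""


class CohortLoadError(PolarMaceError):
    """Cohort manifest or per-patient matrix file could not be loaded."""


class DomainError(PolarMaceError, ValueError):
    """Mathematically invalid input to a signal derivation."""


class NotFittedError(PolarMaceError, RuntimeError):
    """A transformer or model was used before fitting."""


class TrainingError(PolarMaceError, RuntimeError):
    """Model training diverged or received an unusable training set."""
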