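"""Exception types raised across the package."""


class TMazeError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(TMazeError, ValueError):
    """A geometry, field, or run configuration violates an invariant."""


class InvalidGradientError(InvalidConfigurationError):
    """Source/sink concentrations cannot produce a valid gradient."""


class SingularPhenotypeError(TMazeError, ValueError):
    """A phenotype at the boundary of the admissible domain (e.g. T_B = 0)."""


class DomainError(TMazeError, ValueError):
    """An input outside the mathematical domain of an operation."""


class StabilityError(TMazeError, RuntimeError):
    """Time step or grid spacing violates the stability criterion of a scheme."""


class UndefinedAccumulationError(DomainError):
    """Accumulation length requested for non-positive chemotactic velocity."""


class UnidentifiableError(TMazeError, RuntimeError):
    """A fit whose data do not constrain the parameter (flat/empty profile)."""


class InsufficientDataError(TMazeError, ValueError):
    """Too few usable data points for the requested estimate."""


class AccuracyWarning(UserWarning):
    """Numerical truncation or masking that may degrade accuracy."""
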