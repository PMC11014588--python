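"""Exception hierarchy for structec.

All errors derive from :class:`StructecError` so callers can catch the
package's failures with a single ``except`` clause.  Numerical failures
(singular operators, improper reductions) carry enough context to locate
the offending frequency, regime or eigenvalue.
"""


class StructecError(Exception):
    """Base class for all structec errors."""


class InvalidParameterError(StructecError, ValueError):
    """A model parameter is non-finite or violates a domain constraint."""


class DomainError(StructecError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class NumericalSingularityError(StructecError, ArithmeticError):
    """A linear operator that must be invertible is numerically singular."""


class IllConditionedDataError(StructecError, ValueError):
    """Observed data produce a rank-deficient regression problem."""


class DegenerateConnectomeError(StructecError, ValueError):
    """Structural connectivity has no informative (off-diagonal) weight."""


class InvalidTransformError(StructecError, ValueError):
    """A prior-variance transform violates its positivity constraints."""


class MisalignedSubjectsError(StructecError, ValueError):
    """Subjects do not share a common region set / parameter naming."""


class MisalignedParametersError(StructecError, ValueError):
    """Named parameter blocks of two densities cannot be aligned."""


class InsufficientReplicationError(StructecError, ValueError):
    """A random-effects model needs at least two subjects."""


class ImproperReductionError(StructecError, ArithmeticError):
    """Bayesian model reduction produced a non-PSD posterior precision."""


class EmptyGridError(StructecError, ValueError):
    """A hyperparameter grid is empty after applying its constraints."""


class DegeneratePosteriorError(StructecError, ArithmeticError):
    """An approximate posterior has a singular covariance."""


class DegenerateModelError(StructecError, ArithmeticError):
    """A linear-Gaussian model has a singular marginal covariance."""


class InfeasibleDensityError(StructecError, ValueError):
    """Requested edge density cannot connect the requested graph."""


class InstabilityError(StructecError, ArithmeticError):
    """Numerical integration diverged (non-finite state)."""


class UndefinedCorrelationError(StructecError, ValueError):
    """Correlation is undefined because an input has zero variance."""


class MaskMismatchError(StructecError, ValueError):
    """Directed-FC estimates with different masks cannot be combined."""


class ConfigError(StructecError, ValueError):
    """A run configuration contains unknown or invalid keys."""
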