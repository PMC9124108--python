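"""Exception hierarchy shared across the package.

Every error raised deliberately by gwanfis derives from :class:`GwanfisError`
so that callers (and the CLI) can distinguish domain failures from bugs.
"""


class GwanfisError(Exception):
    """Base class for all gwanfis errors."""


class InvalidInputError(GwanfisError, ValueError):
    """Input data violates a documented precondition (empty matrix, bad labels...)."""


class ParseError(InvalidInputError):
    """A delimited-text file could not be parsed; message names the offending cell."""


class InvalidConfigError(GwanfisError, ValueError):
    """A configuration object violates one of its invariants."""


class DimensionMismatchError(GwanfisError, ValueError):
    """Vectors or matrices that must agree in shape do not."""


class DegenerateActivationError(GwanfisError, ArithmeticError):
    """All rule firing strengths are zero; normalization is undefined."""


class UndefinedMetricError(GwanfisError, ValueError):
    """A requested metric is undefined for the given confusion matrix."""
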