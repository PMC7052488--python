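"""Exception hierarchy used across the package."""


class MilatomsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MilatomsError, ValueError):
    """A configuration or parameter value is invalid."""


class DataError(MilatomsError, ValueError):
    """Input data violates a precondition (shape, labels, finiteness)."""


class NumericalError(MilatomsError, ArithmeticError):
    """A numerical routine failed (e.g. singular covariance without shrinkage)."""
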