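"""Exception hierarchy shared across the package."""


class MigrasimError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MigrasimError, ValueError):
    """An argument violates a documented precondition."""


class NumericalError(MigrasimError, ArithmeticError):
    """A numerical routine failed to converge or bracket a solution."""


class EmptyRangeError(MigrasimError, ValueError):
    """A binary range contains no presence cells."""


class SampleSizeError(MigrasimError, ValueError):
    """Observed sample too small for the validation procedure (n >= 6)."""


class InvalidMetricError(MigrasimError, KeyError):
    """Requested journey metric is not available."""


class SchemaError(MigrasimError, ValueError):
    """An input file does not conform to its declared schema."""


class DomainError(MigrasimError, ValueError):
    """A geometric operation left the valid spatial domain."""
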