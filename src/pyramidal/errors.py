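"""Exception types shared across the package."""


class PyramidalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PyramidalError, ValueError):
    """An argument is outside the domain of an operation."""


class InvalidStateError(PyramidalError, ValueError):
    """A state object violates its invariants."""


class ConfigurationError(PyramidalError, ValueError):
    """A configuration document or option set is invalid."""


class ComparisonError(PyramidalError, ValueError):
    """Two simulation results cannot be compared (e.g. grid mismatch)."""


class FixedPointError(PyramidalError, ArithmeticError):
    """Invalid fixed-point operation (e.g. division by a zero raw value)."""
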