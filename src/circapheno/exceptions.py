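"""Package-wide exception types."""


class CircaphenoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CircaphenoError, ValueError):
    """Invalid parameter or configuration value."""


class NumericalInstabilityError(CircaphenoError, ArithmeticError):
    """A numerical routine diverged (e.g. an unstable Euler step)."""


class TooShortError(CircaphenoError, ValueError):
    """A time series is too short to support the requested analysis."""


class DivisionGuardError(CircaphenoError, ZeroDivisionError):
    """A normalizing denominator fell below machine tolerance."""
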