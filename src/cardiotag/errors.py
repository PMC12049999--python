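"""Exception hierarchy."""


class CardiotagError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardiotagError):
    """Invalid configuration or parameter ranges."""


class DomainError(CardiotagError):
    """Input outside the physical/geometric domain of an operation."""


class FormatError(CardiotagError):
    """File content incompatible with the package's conventions."""


class MeasurementError(CardiotagError):
    """A measurement probe could not produce a well-defined result."""
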