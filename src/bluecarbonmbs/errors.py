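"""Exception hierarchy shared across the package."""


class BlueCarbonError(Exception):
    """Base class for package errors."""


class ConfigurationError(BlueCarbonError, ValueError):
    """A configuration field is out of range or inconsistent."""


class InputValidationError(BlueCarbonError, ValueError):
    """An input table violates its column contract; message cites the row."""


class ImputationError(BlueCarbonError, ValueError):
    """Carbon-content imputation cannot proceed (no measured content at all)."""


class SpeciesLookupError(BlueCarbonError, KeyError):
    """A landings species is absent from the carbon-content table."""


class DomainError(BlueCarbonError, ValueError):
    """A quantity is outside the mathematical domain of an operation."""
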