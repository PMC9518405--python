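"""Exception hierarchy shared across the package."""


class EcgwellError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EcgwellError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(EcgwellError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ValidationError(EcgwellError, ValueError):
    """Input data fails a domain validation rule (e.g. HI outside 1..5)."""


class DimensionError(EcgwellError, ValueError):
    """Shape mismatch between a fitted model and the data it is applied to."""


class ExtractionError(EcgwellError, RuntimeError):
    """A feature-extractor family failed on a segment."""
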