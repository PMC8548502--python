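"""Exception types shared across the package."""


class PlastiselError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlastiselError, ValueError):
    """Invalid generator or pipeline configuration."""


class ValidationError(PlastiselError, ValueError):
    """Input data violates a documented invariant."""
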