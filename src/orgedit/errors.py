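"""Exception hierarchy shared across the package."""


class OrgeditError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(OrgeditError, ValueError):
    """An operation received an out-of-domain argument."""


class DesignError(OrgeditError):
    """Sample design is inconsistent with the data or the truth table."""


class GenerationError(OrgeditError):
    """The synthetic-data generator could not satisfy its constraints."""


class InputError(OrgeditError):
    """Malformed or inconsistent input tables."""


class AnnotationError(OrgeditError):
    """Site or intron annotation inconsistent with the reference."""


class ConfigError(OrgeditError):
    """Run configuration failed validation."""
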