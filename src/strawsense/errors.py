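"""Exception types shared across the package."""


class StrawsenseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StrawsenseError):
    """A required column or config key is missing or unresolvable."""


class ValidationError(StrawsenseError):
    """Input rows violate the typed invariants (out-of-range values, duplicates)."""

    def __init__(self, message: str, offenses: list | None = None):
        super().__init__(message)
        # list of (row_number, column, value, reason) tuples
        self.offenses = offenses or []


class ConfigError(StrawsenseError):
    """An impossible or inconsistent configuration."""


class DependencyError(StrawsenseError):
    """A pipeline stage was requested without its required inputs."""
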