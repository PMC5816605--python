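"""Package-wide error types.

Errors are split by origin: bad configuration, bad input data, and
quality-based exclusion (a participant whose recording is unusable).
"""


class DyadsyncError(Exception):
    """Base class for all package errors."""


class ConfigError(DyadsyncError):
    """A configuration value violates its contract; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class InputError(DyadsyncError):
    """Malformed or contract-violating input data."""


class QualityError(DyadsyncError):
    """Recording quality below the usable threshold; exclude the participant."""
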