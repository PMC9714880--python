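"""Exception hierarchy for the action-regulation simulator."""


class ActionRegError(Exception):
    """Base class for all simulator errors."""


class InvalidParameterError(ActionRegError, ValueError):
    """A model parameter is non-finite or outside its admissible range."""


class WiringError(ActionRegError):
    """A projection or input vector does not match the field sizes it connects."""


class DivergenceError(ActionRegError):
    """A field's activity left the configured bounds during integration."""

    def __init__(self, field_name: str, message: str = ""):
        self.field_name = field_name
        super().__init__(message or f"field '{field_name}' diverged during integration")


class ConfigurationError(ActionRegError):
    """The run configuration is incomplete or self-contradictory."""


class MetricError(ActionRegError):
    """A behavioral metric cannot be computed from the given trajectory."""
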