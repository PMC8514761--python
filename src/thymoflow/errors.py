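"""Exception hierarchy shared across the pipeline."""


class ThymoflowError(Exception):
    """Base class for all package errors."""


class PanelError(ThymoflowError):
    """A required marker is missing or cannot be resolved through aliases."""


class FormatError(ThymoflowError):
    """A file does not parse under the declared format."""


class StateError(ThymoflowError):
    """An operation was applied to data in the wrong scale state."""


class ConfigError(ThymoflowError):
    """An invalid specification or configuration value."""


class DataError(ThymoflowError):
    """Input data violates a precondition (empty selection, missing column...)."""


class GateFitError(ThymoflowError):
    """Automatic threshold placement failed for a gate node."""


class AlignmentError(ThymoflowError):
    """Per-event vectors (labels, masks) are not aligned with the event table."""
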