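"""Exception hierarchy shared across the package."""


class VqsvddError(Exception):
    """Base class for package errors."""


class ConfigurationError(VqsvddError, ValueError):
    """Invalid configuration values or inconsistent options."""


class DimensionError(VqsvddError, ValueError):
    """Array shapes incompatible with an operation."""


class FormatError(VqsvddError, ValueError):
    """On-disk data not in the expected layout."""


class PlacementError(VqsvddError, RuntimeError):
    """A synthetic anomaly cannot be placed inside a lung field."""


class StateError(VqsvddError, RuntimeError):
    """Operation called before required state exists (e.g. no center yet)."""
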