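"""Exception hierarchy shared across the package."""


class AlshiftError(Exception):
    """Base class for package-specific errors."""


class ParameterError(AlshiftError, ValueError):
    """A generator or config parameter is outside its documented range."""


class ConfigurationError(AlshiftError, ValueError):
    """Mutually inconsistent configuration (shapes, vocabularies, layers)."""


class StructureError(AlshiftError, ValueError):
    """An on-disk dataset does not follow the expected directory layout."""


class StateError(AlshiftError, RuntimeError):
    """An operation was requested in an invalid state (e.g. pool exhausted)."""


class TrainingError(AlshiftError, RuntimeError):
    """Training cannot proceed (e.g. degenerate single-class input)."""
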