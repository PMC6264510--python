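"""Exception hierarchy shared across the package."""


class AflpopError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AflpopError, ValueError):
    """A file could not be parsed into the expected structure."""


class ValidationError(AflpopError, ValueError):
    """Input data violates a documented invariant."""


class EmptyDataError(AflpopError, ValueError):
    """A filter or selection left no usable data."""


class ConfigError(AflpopError, ValueError):
    """A configuration object is internally inconsistent."""
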