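"""Exception hierarchy shared across the package."""


class BlennymineError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BlennymineError, ValueError):
    """A parameter value is outside its documented valid range."""


class InputError(BlennymineError, ValueError):
    """An input record or file is malformed or inconsistent."""


class ConfigError(BlennymineError, ValueError):
    """A configuration file or option is invalid."""


class FitError(BlennymineError, RuntimeError):
    """A model fit cannot be attempted (insufficient or degenerate data)."""
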