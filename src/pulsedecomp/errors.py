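"""Exception types shared across the package."""


class PulseDecompError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PulseDecompError, ValueError):
    """A parameter violates its documented domain (non-positive geometry,
    out-of-range pressure, malformed grid, ...)."""


class ModelInconsistencyError(PulseDecompError, RuntimeError):
    """The forward model produced a physically inconsistent state
    (component pressure outside [diastole, systole], non-monotone arrival
    times).  The message names the offending term."""


class ConfigError(PulseDecompError, ValueError):
    """A configuration file failed schema validation; the message names the
    offending key."""
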