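"""Exception hierarchy shared across the package."""


class SeasonRhythmError(Exception):
    """Base class for all package-specific errors."""


class InputError(SeasonRhythmError):
    """Raised when input data violate a precondition (bad dates, no events, ...)."""


class FitError(SeasonRhythmError):
    """Raised when a model cannot be estimated (rank deficiency, separation, ...)."""


class ConfigError(SeasonRhythmError):
    """Raised when a simulation or analysis configuration is infeasible."""
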