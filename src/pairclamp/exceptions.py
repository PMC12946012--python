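"""Exception types raised across the package."""


class PairclampError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(PairclampError, ValueError):
    """A simulation or analysis parameter violates its documented domain."""


class LowResolutionError(PairclampError, ValueError):
    """Sampling rate too low to resolve the dV/dt detection criterion."""


class MissingFeatureError(PairclampError, ValueError):
    """A required feature is absent (e.g. an all-missing column)."""


class UndefinedCorrelationError(PairclampError, ValueError):
    """Correlation requested against a zero-variance predictor."""
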