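"""Exception types shared across the package."""


class ReflexMorphError(Exception):
    """Base class for package errors."""


class ConfigurationError(ReflexMorphError):
    """A preset, protocol, or study configuration is invalid or incomplete."""


class UndefinedMetricError(ReflexMorphError):
    """A ratio or percentage is requested with a nonpositive denominator."""


class ThresholdNotFoundError(ReflexMorphError):
    """No tested stimulus intensity reached the response criterion."""
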