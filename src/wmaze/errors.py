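"""Exception types raised across the pipeline stages."""


class WmazeError(Exception):
    """Base class for all package errors."""


class ConfigError(WmazeError):
    """Invalid session or run configuration."""


class DegenerateBaselineError(WmazeError):
    """Baseline window outside the recording, or F0 = 0."""


class ConstantBaselineError(WmazeError):
    """Baseline standard deviation is zero; z-scoring would emit infinities."""


class ShortSegmentError(WmazeError):
    """A trial phase spans fewer than two raw samples and cannot be resampled."""


class RateMismatchError(WmazeError):
    """Trace blocks with different sampling rates cannot be combined."""


class MissingPhaseError(WmazeError):
    """No trial in the table possesses the requested phase."""
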