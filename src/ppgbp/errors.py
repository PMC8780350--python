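"""Exception hierarchy for the PPG/BP pipeline.

Every stage raises a subclass of :class:`PPGBPError`; session-level
rejections (quality, missing landmarks) additionally carry a short
machine-readable ``reason`` code so feature tables can record why a
sample was dropped instead of silently losing it.
"""


class PPGBPError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(PPGBPError, ValueError):
    """A parameter violates a documented precondition."""


class InvalidSamplingRateError(InvalidArgumentError):
    """Sampling rate incompatible with the requested filter (cutoff at/above Nyquist)."""


class TooFewBeatsError(PPGBPError):
    """Fewer than three systolic peaks detected; the session is unusable."""

    reason = "too_few_beats"


class UndefinedSkewnessError(PPGBPError):
    """Skewness undefined (zero-variance beat)."""

    reason = "zero_variance"


class NoInflectionError(PPGBPError):
    """No inflection point found on the downstroke; the sample is dropped."""

    reason = "no_inflection"


class UndefinedFeatureError(PPGBPError):
    """A feature ratio is undefined (e.g. non-positive foot intensity for PIR)."""

    reason = "undefined_feature"


class DegenerateComponentError(PPGBPError):
    """PLS deflation hit a zero-covariance component."""


class NoNeighborsError(PPGBPError):
    """All locality weights underflowed; the local model has no support."""


class UnstableLocalFitError(PPGBPError):
    """Effective local sample size too small for the requested components."""


class InvalidCovarianceError(PPGBPError):
    """Covariance matrix has negative eigenvalues beyond tolerance."""


class NumericalError(PPGBPError):
    """A factorization failed even after jitter escalation."""


class TooFewSamplesError(PPGBPError):
    """Subject has too few samples for the requested calibration scheme."""


class SchemaError(PPGBPError):
    """A session CSV or manifest is missing a required column."""
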