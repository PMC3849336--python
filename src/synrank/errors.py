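"""Typed exceptions used across the package."""


class SynrankError(Exception):
    """Base class for all package errors."""


class InputError(SynrankError, ValueError):
    """Malformed or invalid input data / configuration."""


class DegenerateFeatureError(SynrankError, ValueError):
    """A feature is constant (or otherwise unusable) for model fitting."""


class ComplexityGuardError(SynrankError, RuntimeError):
    """An exact/exhaustive routine was asked for an instance too large to enumerate."""


class InsufficientClassError(SynrankError, ValueError):
    """A class has too few samples to estimate class-conditional moments."""


class UndefinedMetricError(SynrankError, ValueError):
    """A performance metric is undefined for the given labels (e.g. single-class AUC)."""
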