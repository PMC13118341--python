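"""Exception hierarchy.

All package-specific errors derive from :class:`TrayIntakeError` so callers
can catch one base class; subclasses distinguish configuration problems,
malformed data, and statistically degenerate situations.
"""


class TrayIntakeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(TrayIntakeError, ValueError):
    """An invalid parameter object (mixture weights, confusion rows, ...)."""


class DataError(TrayIntakeError, ValueError):
    """A malformed record or table (tare above gross weight, bad schema, ...)."""


class CompositionLookupError(TrayIntakeError, LookupError):
    """A food class missing from the composition table."""


class MaskModelLookupError(TrayIntakeError, LookupError):
    """A (food class, view) pair missing from the mask-area model."""


class UndefinedFractionError(TrayIntakeError, ZeroDivisionError):
    """A consumed fraction requested for a tray with zero served weight."""


class InsufficientDataError(TrayIntakeError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateResampleError(TrayIntakeError, RuntimeError):
    """The bootstrap statistic failed on too many resamples."""


class CalibrationError(TrayIntakeError, ValueError):
    """Geometric calibration impossible (no solids, zero observed area)."""


class SplitError(TrayIntakeError, ValueError):
    """A train/validation/test split cannot be formed."""


class PairingError(TrayIntakeError, ValueError):
    """Pre- and post-meal observations of one tray cannot be matched."""


class PredictionError(TrayIntakeError, ValueError):
    """No usable view observation for a weight prediction."""
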