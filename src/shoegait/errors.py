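"""Exception hierarchy for the shoegait pipeline."""


class GaitError(Exception):
    """Base class for all shoegait errors."""


class FormatError(GaitError):
    """A sensor log file does not have the expected layout."""


class DataError(GaitError):
    """A stream violates a data invariant (non-monotone time, bad quaternion...)."""


class UsageError(GaitError):
    """An operation was called with inconsistent or empty arguments."""


class ConfigurationError(GaitError):
    """A processing parameter is out of its valid range (e.g. cutoff vs Nyquist)."""


class StationarityError(GaitError):
    """A supposedly stationary acceleration sample is not close to gravity."""


class ConvergenceError(GaitError):
    """Iterative calibration failed to converge; carries the last iterate."""

    def __init__(self, message, last_model=None):
        super().__init__(message)
        self.last_model = last_model


class IdentifiabilityError(GaitError):
    """Posture set too small or too degenerate to identify gains and biases."""


class OffsetError(GaitError):
    """No unloaded samples available for force offset removal."""


class SegmentationError(GaitError):
    """Flat-foot / stride segmentation found too little structure to proceed."""
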