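"""Exception hierarchy for synquant.

All domain errors derive from :class:`SynquantError` so callers can catch
one base class; specific subclasses carry the quantity that made the
operation undefined (e.g. the threshold a failed segmentation used).
"""


class SynquantError(Exception):
    """Base class for all synquant domain errors."""


class CalibrationError(SynquantError):
    """An image file carries no physical calibration and none was supplied."""


class SegmentationError(SynquantError):
    """Thresholding produced an empty or unusable mask.

    Attributes
    ----------
    threshold : float or None
        The intensity threshold that was applied when the failure occurred.
    """

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


class AmbiguityError(SynquantError):
    """A landmark cannot be located uniquely (e.g. flat intensity channel)."""


class UndefinedAxisError(SynquantError):
    """The cell→bead axis is undefined because its endpoints coincide."""


class UndefinedRatioError(SynquantError):
    """A ratio metric has a zero denominator (no fluorescence in reference)."""


class DegenerateWindowError(SynquantError):
    """A fit window contains too few frames for a regression."""
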