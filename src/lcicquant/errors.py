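"""Exception and warning types shared across the package."""


class LcicError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LcicError):
    """A generator or analysis configuration violates its invariants."""


class GeometryError(LcicError):
    """Module geometry could not be realised (e.g. non-overlapping placement failed)."""


class BackgroundError(LcicError):
    """No admissible tissue-free background rectangle could be found."""


class EmptyRoiError(LcicError):
    """A region of interest contains no pixels; carries the ROI name."""


class MatrixSignalError(LcicError):
    """Matrix median does not exceed background median: the coverage ratio is undefined."""


class ConstantProfileError(LcicError):
    """A brightness profile is constant after detrending; correlation is undefined."""


class NoCellsError(LcicError):
    """No detected cells fall inside the analysis region; occupancy is undefined."""


class SegmentationWarning(UserWarning):
    """Foreground fraction outside plausibility bounds; an empty mask was returned."""


class SaturationWarning(UserWarning):
    """More than the allowed fraction of a ROI sits at the bit-depth ceiling."""


class ContourClippedWarning(UserWarning):
    """The thickened sampling contour exits the image; samples were clipped to the border."""


class RoiClippedWarning(UserWarning):
    """Module components extended outside the total region and were clipped to it."""
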