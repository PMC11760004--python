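"""Exception hierarchy for the marbling-fineness pipeline."""


class MarbleFineError(Exception):
    """Base class for all marblefine errors."""


class DegenerateHistogram(MarbleFineError):
    """All ROI pixels share one intensity; Otsu thresholding is undefined."""


class EmptyMarbling(MarbleFineError):
    """No fat particles in the mask; cumulative statistics are undefined."""


class InvalidStepSize(MarbleFineError):
    """ROI bounding box is smaller than the requested tiles-per-axis count."""


class NoTilesIncluded(MarbleFineError):
    """No tile meets the minimum ROI coverage requirement."""


class InsufficientTiles(MarbleFineError):
    """Fewer than two included tiles; a sample SD needs n >= 2."""


class UndefinedRatio(MarbleFineError):
    """Denominator index is zero (F8 = F2b/F7 with F7 = 0)."""


class MissingScale(MarbleFineError):
    """A pixels-per-cm calibration is required but was not supplied."""


class InsufficientSample(MarbleFineError):
    """Too few observations or groups for the requested statistical test."""


class ZeroWithinVariance(MarbleFineError):
    """All within-group variances are zero; the F statistic is undefined."""


class UnreachableFraction(MarbleFineError):
    """Requested blob radius cannot fit inside the ROI."""


class ConfigError(MarbleFineError):
    """A run-configuration field is missing or outside its domain."""


class PairingError(MarbleFineError):
    """Input images and ROI masks cannot be paired one-to-one."""
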