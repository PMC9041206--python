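"""Exception hierarchy for the scanning-microscope toolkit."""


class IncuscanError(Exception):
    """Base class for all package errors."""


class CalibrationError(IncuscanError):
    """Landmark or optics calibration input is unusable."""


class InconsistentLandmarksError(CalibrationError):
    """Vertical and horizontal well-diameter estimates disagree too much."""


class DegenerateLandmarksError(CalibrationError):
    """Landmarks with zero extent (coincident points)."""


class NoGraticuleError(CalibrationError):
    """No significant periodicity found in a graticule image."""


class NoEdgeError(CalibrationError):
    """No usable step edge found in a slant-edge ROI."""


class GCodeError(IncuscanError):
    """Malformed G-code or GRBL setting line."""


class TravelLimitError(IncuscanError):
    """Commanded move exceeds the configured stage travel."""


class LowConfidenceError(IncuscanError):
    """Translation estimate below the confidence threshold."""


class ConfigError(IncuscanError):
    """Configuration file failed validation."""
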