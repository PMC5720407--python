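"""Exception hierarchy.

Every error raised by the library derives from :class:`MatchdoseError` so the
CLI can distinguish processing failures (exit 1) from usage mistakes (exit 2,
handled by click).
"""


class MatchdoseError(Exception):
    """Base class for all matchdose errors."""


class FormatError(MatchdoseError):
    """An input file violates the expected format (bit depth, channels, header)."""


class CalibrationError(MatchdoseError):
    """Sensitometric data is non-monotone or otherwise unusable."""


class OutOfRangeError(MatchdoseError):
    """An optical density or dose falls outside the calibrated range."""


class DetectionError(MatchdoseError):
    """Fiducial pinpricks could not be located unambiguously."""


class GeometryError(MatchdoseError):
    """Fiducial or profile geometry is degenerate (coincident points, no overlap)."""


class ExtentError(MatchdoseError):
    """A requested region does not fit inside the image."""


class ConfigError(MatchdoseError):
    """A simulation or run configuration is invalid."""
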