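"""Exception hierarchy for gravsep."""


class GravsepError(Exception):
    """Base class for all package-specific errors."""


class InvalidFilterError(GravsepError, ValueError):
    """Filter specification is unusable (e.g. cut-off at or above Nyquist)."""


class TooShortError(GravsepError, ValueError):
    """Recording or averaging window is too short for the requested operation."""


class CalibrationError(GravsepError, ValueError):
    """Static calibration is under-determined or fails the 1 g identity check."""


class ProfileError(GravsepError, ValueError):
    """Synthetic day profile is inconsistent (e.g. overlapping bouts)."""


class RecordingParseError(GravsepError, ValueError):
    """Raw recording file could not be parsed; message names the offending line."""


class ConfigError(GravsepError, ValueError):
    """Run configuration failed schema validation."""
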