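"""Exception hierarchy for liftpattern.

Everything derives from :class:`LiftPatternError` so callers can catch the
package's failures with one except clause; parse/validation/segmentation
errors are kept distinct because the CLI maps them to different messages.
"""


class LiftPatternError(Exception):
    """Base class for all liftpattern errors."""


class ValidationError(LiftPatternError, ValueError):
    """Invalid argument or malformed in-memory data."""


class TrajectoryParseError(LiftPatternError):
    """A trajectory file could not be parsed; message names the offending
    line or XML element."""


class SegmentationError(LiftPatternError):
    """Fewer repetition cycles detected than requested."""


class CalibrationError(LiftPatternError):
    """Fuzzy-output calibration failed (singular activation basis)."""
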