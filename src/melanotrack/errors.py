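"""Exception hierarchy.

All user-facing errors derive from :class:`MelanotrackError` so callers can
catch the package's failures with a single except clause; parameter problems
additionally derive from ``ValueError``.
"""


class MelanotrackError(Exception):
    """Base class for all errors raised by melanotrack."""


class InvalidParameterError(MelanotrackError, ValueError):
    """A simulation or analysis parameter violates its constraints."""


class TrackFormatError(MelanotrackError):
    """A track table does not conform to the declared dialect."""


class DuplicateRecordError(TrackFormatError):
    """The same (track, frame) pair appears more than once."""


class ParseError(TrackFormatError):
    """A row holds a non-numeric coordinate; carries the offending row number."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class GapError(TrackFormatError):
    """A track has missing frames and gap tolerance was not requested."""


class DescriptorError(MelanotrackError):
    """A kinematic descriptor is undefined for the given trajectory."""


class CalibrationError(MelanotrackError):
    """Frontier calibration failed (e.g. too many degenerate references)."""


class PipelineError(MelanotrackError):
    """A pipeline stage failed; message is prefixed with the stage name."""
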