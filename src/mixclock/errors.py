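"""Exception hierarchy.

Every error raised by the library derives from :class:`MixclockError` so the
CLI can map failures onto stable exit codes (bad input/config vs. internal).
"""


class MixclockError(Exception):
    """Base class for all mixclock errors."""


class InputError(MixclockError):
    """Missing/unreadable input, or a value outside the data's span."""


class ParameterError(MixclockError):
    """A parameter violates its documented precondition."""


class FormatError(MixclockError):
    """Input parses but has the wrong shape/columns/dimensions."""


class SegmentationError(MixclockError):
    """Reactor segmentation produced an unusable (e.g. empty) mask."""


class DegenerateMaskError(MixclockError):
    """Mask covers fewer than two pixels; the spatial SD is meaningless."""


class DetectionError(MixclockError):
    """Tracer-addition detection found no qualifying deviation."""


class DegenerateBandError(MixclockError):
    """Tolerance band has zero width (final value is 0 under relative_final)."""
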