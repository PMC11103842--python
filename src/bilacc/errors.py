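"""Exception hierarchy for the bilateral accelerometry pipeline.

All errors raised by the package derive from :class:`BilaccError`, so callers
can catch a single base class at pipeline level while tests discriminate the
specific failure mode.
"""


class BilaccError(Exception):
    """Base class for all package errors."""


class FormatError(BilaccError):
    """A file does not conform to the expected dialect (header, columns)."""


class RangeError(BilaccError):
    """A value lies outside its contractual range (8-bit counts, score bounds)."""


class TooShortError(BilaccError):
    """A series is too short for the requested operation."""


class ShapeError(BilaccError):
    """Array arguments have incompatible lengths or shapes."""


class ParameterError(BilaccError):
    """A configuration parameter is invalid (e.g. cutoff at or above Nyquist)."""


class ConsistencyError(BilaccError):
    """Cohort metadata contradicts itself (duplicate sessions, side changes)."""


class EmptyAfterTrimError(BilaccError):
    """Trailing-idle removal would leave an empty series."""


class InsufficientOverlapError(BilaccError):
    """The two arms overlap for less than the configured minimum duration."""


class DegenerateError(BilaccError):
    """A statistic is undefined on the input (e.g. zero rank variance)."""


class EmptyError(BilaccError):
    """An aggregation was requested on an empty group."""
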