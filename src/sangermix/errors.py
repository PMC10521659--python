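"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`SangermixError`
so callers (and the CLI) can catch one type.  The pipeline driver attaches the
name of the failing stage to the ``stage`` attribute.
"""


class SangermixError(Exception):
    """Base class for all package errors."""

    #: pipeline stage in which the error occurred (set by ``quantify``)
    stage: str | None = None


class ValidationError(SangermixError):
    """An object violates its structural invariants."""


class TraceParseError(SangermixError):
    """A chromatogram file could not be parsed."""


class ReadTooShortError(SangermixError):
    """A read has fewer base calls than the trim window requires."""


class InsufficientAnchorsError(SangermixError):
    """Fewer anchor points than the required minimum were found."""


class DivergenceError(SangermixError):
    """The reference sequences do not diverge inside the quality window."""


class DegenerateContrastError(SangermixError):
    """The two warped references are indistinguishable on the support."""


class NoGainAnchorsError(SangermixError):
    """No anchor point has a usable (nonzero) reference amplitude."""


class UnknownPromoterError(SangermixError):
    """Promoter name not in the bundled calibration table."""


class DegenerateDesignError(SangermixError):
    """A recovery experiment needs at least two distinct true ratios."""
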