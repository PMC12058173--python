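"""Exception hierarchy.

All errors derive from :class:`WaveletTFError` so callers can catch the
package's failures with a single ``except``; each also subclasses the
closest built-in (``ValueError`` / ``IOError``) for idiomatic handling.
"""


class WaveletTFError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(WaveletTFError, ValueError):
    """A parameter violates an operation's precondition."""


class SignalTooShortError(WaveletTFError, ValueError):
    """The input trace is shorter than an analysis wavelet."""


class UnsupportedMeasureError(WaveletTFError, ValueError):
    """The requested operation does not apply to this measure (e.g. complex)."""


class DegenerateBaselineError(WaveletTFError, ValueError):
    """A divisive/normalized baseline value is zero."""


class DomainError(WaveletTFError, ValueError):
    """Values outside the mathematical domain of the operation (e.g. log of <= 0)."""


class MalformedFileError(WaveletTFError, IOError):
    """A file is missing required fields or metadata."""


class UnsupportedDesignError(WaveletTFError, ValueError):
    """The recording's event structure is not the supported one-trigger-per-epoch design."""


class IncompatibleResultsError(WaveletTFError, ValueError):
    """Two results do not share axes/labels/measure and cannot be combined."""
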