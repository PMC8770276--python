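"""Exception hierarchy for eegpref.

Every error raised by the package derives from :class:`EegprefError`, so
callers can catch one type at pipeline boundaries while tests can assert
on the specific failure mode.
"""


class EegprefError(Exception):
    """Base class for all eegpref errors."""


class FormatError(EegprefError):
    """Unknown or unreadable file format."""


class MontageMismatchError(EegprefError):
    """Channel labels in a file do not match the expected montage."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class MarkerError(EegprefError):
    """Missing, duplicated, or out-of-order event markers."""


class ParameterError(EegprefError, ValueError):
    """Invalid parameter value (bad filter edges, empty selections, ...)."""


class DomainError(EegprefError, ValueError):
    """Input outside the mathematical domain of a feature (e.g. a
    non-positive band power fed to a normalized asymmetry index)."""


class UndefinedFeatureError(EegprefError):
    """A feature value is undefined for this input (zero variance, zero
    total power, vanishing log-denominator). Raised rather than letting
    NaN/Inf propagate into feature tables."""


class ClassBalanceError(EegprefError):
    """An operation requires both classes but received only one."""
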