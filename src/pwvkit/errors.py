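"""Exception hierarchy shared across pwvkit modules."""


class PwvKitError(Exception):
    """Base class for all pwvkit errors."""


class InvalidConfigError(PwvKitError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class InvalidArgumentError(PwvKitError, ValueError):
    """An operation received an argument outside its precondition."""


class UnsupportedRatioError(InvalidArgumentError):
    """Resampling ratio is not expressible as a small rational p/q."""


class UndefinedCorrelationError(PwvKitError):
    """ZNCC is undefined because one input has zero variance."""


class InsufficientOverlapError(PwvKitError):
    """Less than the minimum usable overlap remains after edge trimming."""


class UndefinedRateError(PwvKitError):
    """Heart rate cannot be computed from fewer than two peaks."""


class EmptyResultError(PwvKitError):
    """No valid beat pairs survived the pipeline.

    The total number of candidate pairs is preserved on ``n_total``.
    """

    def __init__(self, message: str, n_total: int = 0):
        super().__init__(message)
        self.n_total = n_total


class RecordingFormatError(PwvKitError, ValueError):
    """A recording file does not conform to the on-disk dialect.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
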