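"""Exception hierarchy.

Exit-code mapping in the CLI distinguishes config errors (:class:`ConfigError`),
data errors (:class:`DataError` and subclasses) and numerical failures
(:class:`ConvergenceError`).
"""


class StimtrajError(Exception):
    """Base class for all package errors."""


class ConfigError(StimtrajError):
    """Invalid run configuration."""


class DataError(StimtrajError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A table file does not match the declared CSV dialect."""


class RowError(DataError):
    """A single data row is invalid.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(DataError):
    """Cross-field or cross-table invariant violated."""


class UndefinedFeaturesError(DataError):
    """Treatment features requested for an all-zero (stimulant-naive) trajectory."""


class GenerationError(StimtrajError):
    """The synthetic-cohort generator could not satisfy its spec."""


class DegenerateDataError(DataError):
    """A computation is undefined on this input (zero variance, no events, ...)."""


class ConvergenceError(StimtrajError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""
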