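"""Exception hierarchy shared across the package."""

from __future__ import annotations


class RegdomError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(RegdomError):
    """A network file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UsageError(RegdomError):
    """The caller violated a precondition (bad flag value, empty input, ...)."""


class SolverTimeout(RegdomError):
    """An exact solver hit its time or iteration limit.

    ``incumbent`` holds the best feasible solution found so far, if any
    (a :class:`regdom.result.DominatingSetResult` or ``None``).
    """

    def __init__(self, message: str, incumbent=None):
        self.incumbent = incumbent
        super().__init__(message)


class InternalSolverError(RegdomError):
    """The backend returned a state that should be impossible (e.g. infeasible
    domination model, which always admits the all-ones solution)."""
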