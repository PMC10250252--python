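"""Exception hierarchy shared across the package."""


class AngioQcaError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(AngioQcaError, ValueError):
    """A phantom / study specification violates its invariants."""


class InvalidReferenceError(AngioQcaError, ValueError):
    """A QCA reference record is malformed (missing roles, non-parallel calipers...)."""


class InvalidInputError(AngioQcaError, ValueError):
    """Inputs to a measurement are inconsistent (shape mismatch, bad labels...)."""


class DomainError(AngioQcaError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class InsufficientDataError(AngioQcaError, ValueError):
    """Too few observations for the requested statistic."""


class EmptyInputError(InsufficientDataError):
    """An aggregation received no usable observations."""


class ConvergenceError(AngioQcaError, RuntimeError):
    """An iterative calibration failed to reach its target.

    Carries ``best_value``, the closest realized value, so callers can report
    how far the search got.
    """

    def __init__(self, message: str, best_value: float | None = None):
        super().__init__(message)
        self.best_value = best_value


class InvalidRubricError(AngioQcaError, ValueError):
    """A GSS rubric does not sum to 100 points or has duplicate ids."""
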