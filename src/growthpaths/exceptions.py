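"""Exception hierarchy shared across the package."""


class GrowthPathsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GrowthPathsError, ValueError):
    """Invalid input values (non-finite z-scores, negative durations, ...)."""


class SchemaError(GrowthPathsError, KeyError):
    """A required column is missing or unmapped for a cohort."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return GrowthPathsError.__str__(self)


class RankDeficiencyError(GrowthPathsError, ValueError):
    """Design matrix is not of full column rank; names the collinear columns."""


class SeparationError(GrowthPathsError, RuntimeError):
    """Logistic likelihood is maximized at infinity (complete/quasi separation)."""


class ConvergenceError(GrowthPathsError, RuntimeError):
    """Iterative fit failed to converge within the iteration budget."""


class CycleError(GrowthPathsError, ValueError):
    """The structural graph contains a directed cycle."""
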