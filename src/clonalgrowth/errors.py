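"""Exception hierarchy for the analysis pipeline.

All package errors derive from :class:`ClonalGrowthError` so callers can
catch one base class; the subclasses distinguish contract violations
(caller bugs) from data-driven failures (degenerate series, fits that do
not converge, thresholds never crossed).
"""


class ClonalGrowthError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(ClonalGrowthError, ValueError):
    """A precondition or type invariant was violated by the caller."""


class DomainError(ClonalGrowthError, ValueError):
    """Evaluation requested outside a model family's valid domain."""


class DegenerateSeriesError(ClonalGrowthError, ValueError):
    """A series is constant, all-zero, or otherwise unfittable."""


class NonConvergenceError(ClonalGrowthError, RuntimeError):
    """No optimisation start converged; carries best-attempt diagnostics."""

    def __init__(self, message, best_params=None, best_rss=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_rss = best_rss


class ExtractionError(ClonalGrowthError, RuntimeError):
    """A phenological parameter could not be located inside the window."""

    def __init__(self, message, parameter=None):
        super().__init__(message)
        self.parameter = parameter


class SchemaError(ClonalGrowthError, ValueError):
    """An input table is missing columns or contains invalid rows."""


class InsufficientDataError(ClonalGrowthError, ValueError):
    """Too few usable observations for the requested statistic."""
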