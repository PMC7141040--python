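"""Exception hierarchy for the semrec pipeline.

Every stage raises a subclass of :class:`SemrecError`, so callers (and the
pipeline orchestrator) can distinguish data problems from programming errors.
"""


class SemrecError(Exception):
    """Base class for all semrec errors."""


class SchemaError(SemrecError):
    """A required column is missing or unresolvable in the input table."""


class RowError(SemrecError):
    """A specific row holds an unparseable numeric or enum value."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ValidationError(SemrecError):
    """A parsed table violates a study-level invariant (e.g. duplicate ids)."""


class MissingCellError(SemrecError):
    """A design cell required by an analysis has no records."""


class DegenerateBaselineError(SemrecError):
    """The depleted baseline is not lighter than the control (B <= 0)."""


class UnstableBaselineError(SemrecError):
    """Too many bootstrap replicates had a non-positive denominator."""


class ConfigError(SemrecError):
    """A synthetic-data or run configuration violates its invariants."""


class DesignError(SemrecError):
    """A model design is unusable (empty factor level, saturated model...)."""


class SingularDesignError(DesignError):
    """The model matrix is rank deficient (constant regressor, collinearity)."""


class DegenerateVarianceError(SemrecError):
    """A variance-homogeneity test received a zero-variance group."""
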