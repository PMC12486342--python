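"""Exception hierarchy shared across the package."""


class MilkdxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MilkdxError, ValueError):
    """Input values violate a documented precondition."""


class InvalidOutcomeError(InvalidInputError):
    """An outcome label other than allergic/tolerant reached a 2x2 analysis."""


class InvalidProportionError(InvalidInputError):
    """A value expected to be a proportion lies outside [0, 1]."""


class EmptyAnalysisError(InvalidInputError):
    """No non-missing (value, outcome) pairs remain after pairwise deletion."""


class DegenerateRocError(MilkdxError):
    """A ROC analysis was requested with an empty outcome class."""

    def __init__(self, missing_class: str):
        self.missing_class = missing_class
        super().__init__(f"ROC analysis degenerate: no subjects in class {missing_class!r}")


class InvalidCutoffPairError(InvalidInputError):
    """Rule-out cutoff exceeds the rule-in cutoff."""


class ConfigurationError(MilkdxError):
    """A cohort or analysis configuration is incomplete or inconsistent."""


class UnsupportedCaseError(MilkdxError):
    """A closed-form shortcut was requested outside its domain of validity."""


class InvalidTableError(InvalidInputError):
    """A contingency table has a zero margin or malformed cells."""


class SchemaError(MilkdxError):
    """A cohort file is missing mandatory columns or violates structural rules."""


class BootstrapFailureError(MilkdxError):
    """The bootstrapped metric was undefined on more than half the resamples."""
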