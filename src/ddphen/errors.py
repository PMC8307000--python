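"""Exception hierarchy shared across the pipeline.

Two broad classes matter for the CLI: validation problems (bad parameters,
malformed inputs — exit code 2) and data problems (the inputs are well formed
but the computation cannot proceed — exit code 3).
"""


class DDPhenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(DDPhenError):
    """Bad parameters or malformed input; maps to CLI exit code 2."""

    exit_code = 2


class DataError(DDPhenError):
    """Well-formed input on which the computation cannot proceed; exit code 3."""

    exit_code = 3


class InvalidInputError(ValidationError):
    """An argument violates a precondition (e.g. tmin > tmax, NaN temperature)."""


class InvalidConfigError(ValidationError):
    """A configuration object violates its own invariants."""


class NotReachedError(DataError):
    """A degree-day target is never reached within the requested year."""


class UnfillableGapError(DataError):
    """A missing-weather gap exceeds the maximum fillable length."""

    def __init__(self, message, gap_start=None, gap_end=None):
        super().__init__(message)
        self.gap_start = gap_start
        self.gap_end = gap_end


class MissingWeatherError(DataError):
    """A trap check date has no weather (hence no cumulative DD) available."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class SingularDesignError(DataError):
    """The ANOVA design is singular: one or more terms are fully aliased."""

    def __init__(self, message, aliased_terms=()):
        super().__init__(message)
        self.aliased_terms = tuple(aliased_terms)
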