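"""Exception hierarchy for matrix validation, planning and sampling."""


class ReintroplanError(Exception):
    """Base class for all package-specific errors."""


class MatrixValidationError(ReintroplanError, ValueError):
    """A raw matrix failed structural validation."""


class NonSquareError(MatrixValidationError):
    pass


class StageCountError(MatrixValidationError):
    pass


class NegativeEntryError(MatrixValidationError):
    pass


class TransitionBoundError(MatrixValidationError):
    pass


class SurvivalBudgetError(MatrixValidationError):
    pass


class ImprimitiveError(MatrixValidationError):
    pass


class DimensionMismatchError(ReintroplanError, ValueError):
    pass


class ConvergenceError(ReintroplanError, ArithmeticError):
    """The eigensolver failed on a degenerate numerical input."""


class GoalError(ReintroplanError, ValueError):
    """A management goal has out-of-range fields."""


class NoBreedingStageError(ReintroplanError, ValueError):
    """All fertilities are zero; breeding females are undefined."""


class NonPositiveTotalError(ReintroplanError, ValueError):
    pass


class AllZeroReleaseError(ReintroplanError, ValueError):
    pass


class SamplingExhaustedError(ReintroplanError, RuntimeError):
    """Rejection sampling hit its retry cap (infeasible neighborhood)."""


class InsufficientPoolError(ReintroplanError, RuntimeError):
    pass
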