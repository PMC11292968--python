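"""Exception hierarchy.

Everything user-facing derives from :class:`SemilunarError` so the CLI can map
error classes onto exit codes (validation = 3, "no rhythmic series" = 4).
"""


class SemilunarError(Exception):
    """Base class for all package errors."""


class ValidationError(SemilunarError, ValueError):
    """Malformed input: negative counts, non-monotone indices, bad p-values."""


class UnsupportedRegimeError(SemilunarError):
    """An operation requires a light regime it cannot handle (e.g. LL day assignment)."""


class InsufficientDataError(SemilunarError):
    """Too few observed bins / observations for the requested statistic or fit."""


class UndefinedStatisticError(SemilunarError):
    """The statistic is undefined for this input (e.g. all bins missing)."""


class UndefinedBeatError(SemilunarError):
    """Beat period diverges because the diel cycle length equals the lunar-day length."""


class MethodUnavailableError(SemilunarError):
    """A period-detection method cannot run on this series (e.g. JTK beyond its length limit)."""


class RankDeficiencyError(SemilunarError):
    """Regression design matrix is rank deficient (all T-cycle lengths identical)."""


class DegenerateFitError(SemilunarError):
    """Zero residual sum of squares: the Gaussian likelihood (and AICc) is unbounded."""


class ConvergenceError(SemilunarError):
    """Nonlinear fit did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NoRhythmicSeriesError(SemilunarError):
    """A scientific outcome, not a crash: no series passed the significance filter."""
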