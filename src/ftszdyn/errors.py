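"""Exception hierarchy for ftszdyn.

Every error raised by the library derives from :class:`FtszdynError` so
callers can catch analysis failures without also catching programming
errors. Argument-validation failures additionally derive from
``ValueError`` to behave well in generic code.
"""


class FtszdynError(Exception):
    """Base class for all ftszdyn errors."""


class InvalidArgumentError(FtszdynError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(FtszdynError):
    """Too few data points for the requested computation."""


class DegenerateFitError(FtszdynError):
    """A fit produced parameters outside the physically valid region
    (e.g. a nonpositive velocity-vs-concentration slope)."""


class UndefinedPredictionError(FtszdynError):
    """A depletion prediction is undefined (no protein above the
    critical concentration, hence no hydrolysis)."""


class InvalidKineticsError(FtszdynError, ValueError):
    """Kinetic parameters are outside the valid domain (activity <= 0)."""


class DegenerateNormalizationError(FtszdynError):
    """FRAP normalization impossible: reference does not exceed
    background at every frame."""


class FitFailureError(FtszdynError):
    """The nonlinear optimizer failed to converge on every start."""


class UndefinedFractionError(FtszdynError):
    """Pellet fraction undefined because pellet and supernatant
    densities are both zero."""
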