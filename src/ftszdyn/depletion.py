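"""Predicted GTP depletion times for assembly reactions.

Above the critical concentration Cc, every FtsZ subunit in a
protofilament hydrolyzes GTP at the per-enzyme activity a, while the
regenerative picture of steady hydrolysis holds until the nucleotide
pool is gone. Two closed-form quantities follow:

    adjusted concentration (uM) = total FtsZ (uM) - Cc (uM)
    depletion time (s) = GTP (uM) / (adjusted (uM) * a (min^-1)) * 60

The same equations apply to single proteins and coassembled mixtures,
provided the mixture's own fitted (activity, Cc) — obtained from
velocities plotted against TOTAL FtsZ — is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import InvalidArgumentError, InvalidKineticsError, UndefinedPredictionError
from .gtpase import KineticFit

Rounding = Literal["floor", "round"]


@dataclass(frozen=True)
class ReactionSpec:
    """Composition and kinetics of one assembly reaction.

    ``components`` is a list of (name, concentration uM) pairs; a single
    protein is a one-element list. ``kinetics`` must be the fit
    applicable to this composition (the mixture's own fit for mixtures).
    """

    components: tuple[tuple[str, float], ...]
    gtp_conc: float
    kinetics: KineticFit
    label: str = ""

    def __post_init__(self) -> None:
        comps = tuple((str(n), float(c)) for n, c in self.components)
        object.__setattr__(self, "components", comps)
        if any(c < 0 for _, c in comps):
            raise InvalidArgumentError("component concentrations must be >= 0")
        if self.gtp_conc < 0:
            raise InvalidArgumentError("gtp_conc must be >= 0")

    @property
    def total_conc(self) -> float:
        """Total FtsZ concentration (uM), summed over components."""
        return sum(c for _, c in self.components)


@dataclass(frozen=True)
class DepletionPrediction:
    """Prediction for one reaction.

    ``depletion_time_s`` is the raw floating-point time; ``reported_s``
    is the integer-second value under the chosen rounding convention.
    Both are None when the prediction is undefined (``defined`` False:
    no protein above Cc, so no polymer and no hydrolysis).
    """

    total_conc: float
    adjusted_conc: float
    depletion_time_s: float | None
    reported_s: int | None
    defined: bool
    label: str = ""


def adjusted_concentration(spec: ReactionSpec) -> float:
    """Total FtsZ above the critical concentration, floored at 0 (uM)."""
    if spec.kinetics.cc < 0:
        raise InvalidArgumentError("critical concentration must be >= 0")
    return max(spec.total_conc - spec.kinetics.cc, 0.0)


def depletion_time(spec: ReactionSpec, rounding: Rounding = "floor") -> DepletionPrediction:
    """Predict when GTP is exhausted in a reaction.

    Raises :class:`UndefinedPredictionError` when no protein exceeds Cc
    (nothing polymerizes, nothing hydrolyzes) and
    :class:`InvalidKineticsError` for nonpositive activity. GTP = 0
    gives 0 s: the pool is exhausted at the start.

    ``rounding`` selects how the whole-second value is reported:
    ``"floor"`` (default) truncates, ``"round"`` rounds half-up.
    """
    adj = adjusted_concentration(spec)
    if adj == 0.0:
        raise UndefinedPredictionError(
            f"total concentration {spec.total_conc:g} uM does not exceed "
            f"Cc {spec.kinetics.cc:g} uM: no polymerization, no hydrolysis"
        )
    if spec.kinetics.activity <= 0:
        raise InvalidKineticsError("activity must be > 0")
    t = spec.gtp_conc / (adj * spec.kinetics.activity) * 60.0
    reported = math.floor(t) if rounding == "floor" else math.floor(t + 0.5)
    return DepletionPrediction(
        total_conc=spec.total_conc,
        adjusted_conc=adj,
        depletion_time_s=t,
        reported_s=reported,
        defined=True,
        label=spec.label,
    )


def predict(spec: ReactionSpec, rounding: Rounding = "floor") -> DepletionPrediction:
    """Like :func:`depletion_time` but returns an undefined-flagged
    prediction instead of raising when nothing exceeds Cc, so batch
    tables over a concentration series stay computable."""
    try:
        return depletion_time(spec, rounding=rounding)
    except UndefinedPredictionError:
        return DepletionPrediction(
            total_conc=spec.total_conc,
            adjusted_conc=0.0,
            depletion_time_s=None,
            reported_s=None,
            defined=False,
            label=spec.label,
        )


def predict_batch(
    specs: Sequence[ReactionSpec], rounding: Rounding = "floor"
) -> list[DepletionPrediction]:
    """Vector convenience over :func:`predict`."""
    return [predict(s, rounding=rounding) for s in specs]
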