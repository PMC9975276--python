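"""Pellet-fraction statistics from sedimentation densitometry.

High-speed sedimentation separates polymerized FtsZ (pellet) from free
subunits (supernatant); band densitometry of the two fractions gives the
polymerized share as pellet / (pellet + supernatant). Nucleotide
conditions (GTP vs GDP) are compared with a two-sided unpaired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedFractionError

#: QC threshold: warn when pellet+supernatant disagrees with the total
#: lane by more than this relative amount.
TOTAL_MISMATCH_TOLERANCE = 0.25

_VAR_EPSILON = 1e-24  # guards the t statistic when within-group variance is 0
_VAR_TINY = 1e-20  # fractions are O(1); variance below this is float rounding


@dataclass(frozen=True)
class SedimentationSample:
    """Densitometry readings for one sedimentation reaction.

    ``density_total`` (the uncentrifuged control lane) is recorded for
    QC only; the pellet fraction uses pellet and supernatant alone.
    """

    label: str
    nucleotide: str
    density_supernatant: float
    density_pellet: float
    density_total: float | None = None

    def __post_init__(self) -> None:
        for name in ("density_supernatant", "density_pellet"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.density_total is not None and self.density_total < 0:
            raise InvalidArgumentError("density_total must be >= 0")


@dataclass(frozen=True)
class SedimentationResult:
    """Per-condition pellet fractions and the unpaired t-test comparison."""

    fractions_by_condition: dict[str, list[float]]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    t_statistic: float
    p_value: float
    equal_var: bool


def pellet_fraction(sample: SedimentationSample) -> float:
    """Polymerized share: pellet / (pellet + supernatant), in [0, 1]."""
    denom = sample.density_pellet + sample.density_supernatant
    if denom <= 0:
        raise UndefinedFractionError(
            f"sample {sample.label!r}: pellet and supernatant densities are both zero"
        )
    if sample.density_total is not None and sample.density_total > 0:
        mismatch = abs(denom - sample.density_total) / sample.density_total
        if mismatch > TOTAL_MISMATCH_TOLERANCE:
            warnings.warn(
                f"sample {sample.label!r}: pellet+supernatant differs from total "
                f"by {mismatch:.0%}",
                stacklevel=2,
            )
    return sample.density_pellet / denom


def compare_conditions(
    samples: Sequence[SedimentationSample],
    group_a: str = "GTP",
    group_b: str = "GDP",
    equal_var: bool = True,
) -> SedimentationResult:
    """Two-sided unpaired t test on pellet fractions between conditions.

    Student's (equal-variance) test by default; set ``equal_var=False``
    for the Welch variant. Groups whose pooled variance is exactly zero
    are handled with an epsilon guard so perfectly separated groups give
    a finite, astronomically significant t rather than a NaN, and
    identical constant groups give t = 0, p = 1.
    """
    fracs: dict[str, list[float]] = {group_a: [], group_b: []}
    for s in samples:
        if s.nucleotide in fracs:
            fracs[s.nucleotide].append(pellet_fraction(s))
    a, b = np.array(fracs[group_a]), np.array(fracs[group_b])
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 samples per condition")
    if a.var(ddof=1) > _VAR_TINY or b.var(ddof=1) > _VAR_TINY:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    else:
        # zero within-group variance: classic formula with an epsilon floor
        diff = float(a.mean() - b.mean())
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            se = np.sqrt(_VAR_EPSILON * (1 / a.size + 1 / b.size))
            t_stat = diff / se
            dof = a.size + b.size - 2
            p = float(2.0 * stats.t.sf(abs(t_stat), dof))
            p = max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    return SedimentationResult(
        fractions_by_condition={k: list(v) for k, v in fracs.items()},
        means={group_a: float(a.mean()), group_b: float(b.mean())},
        sds={group_a: float(a.std(ddof=1)), group_b: float(b.std(ddof=1))},
        ns={group_a: int(a.size), group_b: int(b.size)},
        t_statistic=t_stat,
        p_value=p,
        equal_var=equal_var,
    )
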