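"""GTPase kinetics from the regenerative NADH-coupled assay.

In the coupled assay, pyruvate kinase regenerates GTP from GDP while
lactate dehydrogenase oxidizes NADH 1:1 with each regeneration, so the
decline of absorbance at 340 nm reports the steady-state GTP hydrolysis
rate at constant GTP. Velocity is linear in FtsZ concentration above the
critical concentration Cc (no oligomers, hence no active sites, below
it), so an ordinary least-squares line through the active points yields
the per-enzyme turnover (the slope, GTP min^-1 FtsZ^-1) and Cc (the
x-intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, InsufficientDataError, InvalidArgumentError

#: NADH molar extinction coefficient at 340 nm, M^-1 cm^-1.
NADH_EXTINCTION = 6220.0

#: Effective optical path length (cm) of a 200 ul reaction in a 96-well plate.
DEFAULT_PATH_CM = 0.56


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A340-vs-time trace for one well of the coupled GTPase assay.

    Parameters
    ----------
    time : array-like of float
        Sample times in seconds, strictly increasing, at least 3 samples.
    a340 : array-like of float
        Absorbance at 340 nm, nonnegative.
    protein_conc : float
        Total FtsZ concentration in the well (uM).
    gtp_conc : float
        Starting GTP concentration (uM).
    label : str
        Free-text well identifier.
    """

    time: np.ndarray
    a340: np.ndarray
    protein_conc: float
    gtp_conc: float
    label: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        a340 = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "a340", a340)
        if time.ndim != 1 or time.shape != a340.shape:
            raise InvalidArgumentError("time and a340 must be 1-D arrays of equal length")
        if time.size < 3:
            raise InvalidArgumentError("an absorbance trace needs at least 3 samples")
        if not np.all(np.diff(time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.any(a340 < 0):
            raise InvalidArgumentError("a340 must be nonnegative")


@dataclass(frozen=True)
class VelocityPoint:
    """One (FtsZ concentration, hydrolysis velocity) pair.

    ``protein_conc`` is in uM; for mixtures it is the TOTAL FtsZ over all
    components. ``velocity`` is in uM GTP min^-1 and is clamped at 0 —
    the coupled assay cannot report negative hydrolysis.
    """

    protein_conc: float
    velocity: float

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise InvalidArgumentError("velocity must be >= 0 (clamp before constructing)")


@dataclass(frozen=True)
class KineticFit:
    """Result of the velocity-vs-concentration regression.

    Attributes
    ----------
    activity : float
        Slope of the regression line, GTP min^-1 FtsZ^-1.
    cc : float
        Critical concentration (uM), the x-intercept ``-intercept/slope``.
    activity_sd, cc_sd : float
        Standard errors; ``cc_sd`` is propagated from the slope/intercept
        covariance by the delta method.
    n_points : int
        Points used in the regression.
    r_squared : float
        Coefficient of determination of the fitted line.
    linear_range : tuple of float
        (min, max) protein concentration among the points used.
    """

    activity: float
    cc: float
    activity_sd: float = float("nan")
    cc_sd: float = float("nan")
    n_points: int = 0
    r_squared: float = float("nan")
    linear_range: tuple[float, float] = (float("nan"), float("nan"))


def velocity_from_trace(
    trace: AbsorbanceTrace,
    epsilon: float = NADH_EXTINCTION,
    path: float = DEFAULT_PATH_CM,
    window: tuple[float, float] | None = None,
) -> VelocityPoint:
    """Convert one A340 trace to a hydrolysis velocity.

    Fits a least-squares line to A340 over ``window`` (seconds; default
    the whole trace) and converts its slope to uM GTP min^-1 through the
    Beer-Lambert law: 1 uM NADH oxidized changes A340 by
    ``epsilon * path * 1e-6``, and NADH oxidation is 1:1 with GTP
    regenerated. A rising trace clamps to velocity 0.

    Raises
    ------
    InvalidArgumentError
        If the window lies outside the trace time span.
    InsufficientDataError
        If fewer than 3 samples fall inside the window.
    """
    if epsilon <= 0 or path <= 0:
        raise InvalidArgumentError("epsilon and path must be positive")
    t, a = trace.time, trace.a340
    if window is not None:
        lo, hi = window
        if lo >= hi or lo < t[0] or hi > t[-1]:
            raise InvalidArgumentError(
                f"window {window} outside trace span ({t[0]}, {t[-1]})"
            )
        mask = (t >= lo) & (t <= hi)
        t, a = t[mask], a[mask]
    if t.size < 3:
        raise InsufficientDataError("velocity fit needs >= 3 points in the window")
    slope_per_s = np.polyfit(t, a, 1)[0]
    slope_per_min = slope_per_s * 60.0
    # dA/dt = -v * epsilon * path * 1e-6 with v in uM/min
    velocity = max(0.0, -slope_per_min) / (epsilon * path) * 1e6
    return VelocityPoint(protein_conc=trace.protein_conc, velocity=velocity)


def _ols_with_cov(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """Slope, intercept, their 2x2 covariance, and R^2 for y = a*x + b."""
    n = x.size
    X = np.column_stack([x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - 2
    if dof > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.full((2, 2), np.nan)
    return float(coef[0]), float(coef[1]), cov, r2


def fit_kinetics(
    points: Sequence[VelocityPoint],
    min_velocity: float = 0.0,
    conc_range: tuple[float, float] | None = None,
) -> KineticFit:
    """Regress hydrolysis velocity on FtsZ concentration.

    Points with ``velocity > min_velocity`` (and, when ``conc_range`` is
    given, with concentration inside it) define the linear range; the
    regression line's slope is the GTPase activity and its x-intercept
    the critical concentration. ``cc_sd`` comes from the delta method:
    for Cc = -b/a, grad = (b/a^2, -1/a) applied to the slope/intercept
    covariance.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points.
    DegenerateFitError
        Nonpositive fitted slope.
    """
    usable = [p for p in points if p.velocity > min_velocity]
    if conc_range is not None:
        lo, hi = conc_range
        usable = [p for p in usable if lo <= p.protein_conc <= hi]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 points with velocity > {min_velocity}, got {len(usable)}"
        )
    x = np.array([p.protein_conc for p in usable])
    y = np.array([p.velocity for p in usable])
    slope, intercept, cov, r2 = _ols_with_cov(x, y)
    if slope <= 0:
        raise DegenerateFitError(f"nonpositive velocity-vs-concentration slope {slope:g}")
    cc = -intercept / slope
    grad = np.array([intercept / slope**2, -1.0 / slope])
    cc_var = float(grad @ cov @ grad)
    return KineticFit(
        activity=slope,
        cc=cc,
        activity_sd=float(np.sqrt(cov[0, 0])),
        cc_sd=float(np.sqrt(cc_var)) if cc_var >= 0 else float("nan"),
        n_points=len(usable),
        r_squared=r2,
        linear_range=(float(x.min()), float(x.max())),
    )


def mixture_activity(
    points: Sequence[VelocityPoint],
    min_velocity: float = 0.0,
    conc_range: tuple[float, float] | None = None,
) -> KineticFit:
    """Fit kinetics for a coassembly mixture.

    Identical computation to :func:`fit_kinetics`; exists as a named
    entry point to enforce the convention that ``protein_conc`` of every
    point is the TOTAL FtsZ concentration summed over mixture components.
    """
    return fit_kinetics(points, min_velocity=min_velocity, conc_range=conc_range)


def pool_replicate_fits(fits: Sequence[KineticFit]) -> KineticFit:
    """Average replicate fits; SD across fits becomes the reported error.

    Mirrors the convention of reporting kinetic parameters as the mean of
    n independent assays with the between-assay standard deviation.
    """
    if len(fits) < 1:
        raise InsufficientDataError("need at least one fit to pool")
    act = np.array([f.activity for f in fits])
    cc = np.array([f.cc for f in fits])
    ddof = 1 if len(fits) > 1 else 0
    return KineticFit(
        activity=float(act.mean()),
        cc=float(cc.mean()),
        activity_sd=float(act.std(ddof=ddof)),
        cc_sd=float(cc.std(ddof=ddof)),
        n_points=len(fits),
        r_squared=float(np.mean([f.r_squared for f in fits])),
        linear_range=(
            float(min(f.linear_range[0] for f in fits)),
            float(max(f.linear_range[1] for f in fits)),
        ),
    )
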