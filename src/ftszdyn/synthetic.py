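"""Synthetic instrument data with known ground truth.

Every downstream analysis stage (GTPase regression, depletion
prediction, light-scattering metrics, FRAP fitting, sedimentation
statistics) gets a parameter-recovery surface: the generators here
produce the four input data kinds from explicit ground-truth parameters,
so tests can check that analysis recovers what was put in.

Defaults reproduce the cyanobacterial-FtsZ study conditions: GTPase
activity 0.59 GTP min^-1 FtsZ^-1 with critical concentration 2.12 uM,
protein series 2-14 uM, 50 uM GTP, 2000 s light-scattering assays, and
FRAP sampling of 3 prebleach plus 30 postbleach frames at 10 s
intervals.

All random generation flows through one seeded ``numpy.random.Generator``;
callers may pass their own, otherwise it derives from ``GroundTruth.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .frap import FRAPTrace, model_frap
from .gtpase import DEFAULT_PATH_CM, NADH_EXTINCTION, AbsorbanceTrace
from .lightscattering import LSTrace
from .sedimentation import SedimentationSample


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a synthetic experiment.

    Attributes
    ----------
    activity : float
        GTPase turnover, GTP min^-1 FtsZ^-1 (> 0).
    cc : float
        Critical concentration, uM (>= 0).
    protein_concs : tuple of float
        FtsZ concentration series for the GTPase assay, uM.
    gtp_conc : float
        Starting GTP, uM.
    ls_amplitude_scale : float
        Light-scattering amplitude per uM of assembly-competent protein
        (a.u. uM^-1).
    ls_rise_rate : float
        First-order assembly rate constant of the LS rise, s^-1.
    disassembly_onset : float or None
        Time (s) at which LS decay begins; None for no disassembly.
    frap_params : tuple
        (r, c_eq1, c_eq2, koff1, koff2) of the two-binding-state model.
    noise_a340, noise_ls, noise_frap, noise_sed : float
        Additive Gaussian noise SDs per channel (absorbance units, a.u.,
        normalized recovery units, and pellet-fraction units).
    seed : int
        Seed for the default generator.
    """

    activity: float = 0.59
    cc: float = 2.12
    protein_concs: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    gtp_conc: float = 50.0
    ls_amplitude_scale: float = 10.0
    ls_rise_rate: float = 0.05
    disassembly_onset: float | None = None
    frap_params: tuple[float, float, float, float, float] = (0.05, 0.5, 0.4, 0.05, 0.005)
    noise_a340: float = 0.002
    noise_ls: float = 1.0
    noise_frap: float = 0.01
    noise_sed: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_concs", tuple(float(c) for c in self.protein_concs))
        if self.activity <= 0:
            raise InvalidArgumentError("activity must be > 0")
        if self.cc < 0:
            raise InvalidArgumentError("cc must be >= 0")
        for name in ("noise_a340", "noise_ls", "noise_frap", "noise_sed"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        r, c1, c2, k1, k2 = self.frap_params
        if not 0 <= r <= 1:
            raise InvalidArgumentError("frap r must be in [0, 1]")
        if c1 < 0 or c2 < 0 or c1 + c2 > 1:
            raise InvalidArgumentError("frap bound fractions must be >= 0 with sum <= 1")
        if k1 <= 0 or k2 <= 0:
            raise InvalidArgumentError("frap koffs must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_gtpase_traces(
    gt: GroundTruth,
    duration: float = 600.0,
    dt: float = 5.0,
    epsilon: float = NADH_EXTINCTION,
    path: float = DEFAULT_PATH_CM,
    a340_start: float = 0.9,
    rng: np.random.Generator | None = None,
) -> list[AbsorbanceTrace]:
    """Simulate coupled-assay A340 traces for the whole protein series.

    Above the critical concentration the hydrolysis velocity is
    ``v = activity * (C - cc)`` uM/min and A340 declines linearly at
    ``v * epsilon * path * 1e-6`` per minute; at or below Cc the trace
    is flat. Gaussian noise (SD ``gt.noise_a340``) is added per sample
    and the result clipped at 0 absorbance.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if epsilon <= 0 or path <= 0:
        raise InvalidArgumentError("epsilon and path must be positive")
    if rng is None:
        rng = gt.rng()
    t = np.arange(0.0, duration + dt / 2, dt)
    traces = []
    for conc in gt.protein_concs:
        v = gt.activity * max(conc - gt.cc, 0.0)  # uM/min
        slope_per_s = -v * epsilon * path * 1e-6 / 60.0
        a340 = a340_start + slope_per_s * t
        if gt.noise_a340 > 0:
            a340 = a340 + rng.normal(0.0, gt.noise_a340, t.size)
        traces.append(
            AbsorbanceTrace(
                time=t,
                a340=np.clip(a340, 0.0, None),
                protein_conc=conc,
                gtp_conc=gt.gtp_conc,
                label=f"sim-{conc:g}uM",
            )
        )
    return traces


def make_ls_trace(
    gt: GroundTruth,
    protein_conc: float,
    duration: float = 2000.0,
    dt: float = 1.0,
    n_baseline: int = 10,
    decay: Literal["linear", "exponential"] = "linear",
    decay_rate: float = 0.002,
    rng: np.random.Generator | None = None,
) -> LSTrace:
    """Simulate one 90-degree light-scattering trace.

    The assembly phase is a saturating exponential
    ``I(t) = A * (1 - exp(-k t))`` with amplitude
    ``A = ls_amplitude_scale * max(protein_conc - cc, 0)`` and rate
    ``k = ls_rise_rate``; below the critical concentration the trace is
    zero-mean noise. If ``gt.disassembly_onset`` is set and falls inside
    the trace, decay begins there: linear with slope ``decay_rate * A``
    per second by default, or exponential with rate ``decay_rate``.
    ``n_baseline`` pre-addition samples (negative times) precede
    nucleotide addition at t = 0. The true onset is stored in
    ``trace.meta["true_onset"]``.
    """
    if not duration > dt > 0:
        raise InvalidArgumentError("require duration > dt > 0")
    if n_baseline < 0:
        raise InvalidArgumentError("n_baseline must be >= 0")
    if rng is None:
        rng = gt.rng()
    t = np.arange(-n_baseline, math.floor(duration / dt) + 1) * dt
    amp = gt.ls_amplitude_scale * max(protein_conc - gt.cc, 0.0)
    signal = np.zeros_like(t)
    post = t >= 0
    signal[post] = amp * (1.0 - np.exp(-gt.ls_rise_rate * t[post]))
    onset = gt.disassembly_onset
    if onset is not None and 0 < onset < duration and amp > 0:
        peak = amp * (1.0 - math.exp(-gt.ls_rise_rate * onset))
        fall = t > onset
        if decay == "linear":
            signal[fall] = peak - decay_rate * amp * (t[fall] - onset)
        else:
            signal[fall] = peak * np.exp(-decay_rate * (t[fall] - onset))
        signal = np.clip(signal, 0.0, None)
    if gt.noise_ls > 0:
        signal = signal + rng.normal(0.0, gt.noise_ls, t.size)
    return LSTrace(
        time=t,
        intensity=signal,
        nucleotide="GTP",
        label=f"sim-ls-{protein_conc:g}uM",
        meta={
            "true_onset": onset if (onset is not None and 0 < onset < duration and amp > 0) else None,
            "true_amplitude": amp,
            "protein_conc": protein_conc,
        },
    )


def make_frap_trace(
    gt: GroundTruth,
    n_pre: int = 3,
    n_post: int = 30,
    dt: float = 10.0,
    prebleach_level: float = 1000.0,
    bg_level: float = 100.0,
    rng: np.random.Generator | None = None,
) -> FRAPTrace:
    """Simulate raw FRAP region intensities from the two-binding-state
    model.

    Postbleach bleach-region intensities follow
    ``bg + (prebleach - bg) * FRAP(t)``; the reference region sits at
    ``prebleach_level`` and the background at ``bg_level`` throughout.
    Gaussian noise with SD ``gt.noise_frap * (prebleach - bg)`` (i.e.
    ``gt.noise_frap`` in normalized units) is added to the bleach
    channel. Time is 0 at the first postbleach frame.
    """
    if n_pre < 1 or n_post < 2:
        raise InvalidArgumentError("need n_pre >= 1 and n_post >= 2")
    if dt <= 0 or prebleach_level <= bg_level or bg_level < 0:
        raise InvalidArgumentError("require dt > 0 and prebleach_level > bg_level >= 0")
    if rng is None:
        rng = gt.rng()
    t_pre = (np.arange(n_pre) - n_pre) * dt
    t_post = np.arange(n_post) * dt
    t = np.concatenate([t_pre, t_post])
    scale = prebleach_level - bg_level
    r, c1, c2, k1, k2 = gt.frap_params
    bleach = np.concatenate(
        [
            np.full(n_pre, prebleach_level),
            bg_level + scale * model_frap(t_post, r, c1, c2, k1, k2),
        ]
    )
    if gt.noise_frap > 0:
        bleach = bleach + rng.normal(0.0, gt.noise_frap * scale, t.size)
    return FRAPTrace(
        time=t,
        bleach=np.clip(bleach, 0.0, None),
        reference=np.full(t.size, prebleach_level),
        background=np.full(t.size, bg_level),
        n_prebleach=n_pre,
        label="sim-frap",
    )


def make_sedimentation_samples(
    fraction_gtp: float,
    fraction_gdp: float,
    n: int = 3,
    noise_sd: float = 0.02,
    seed: int | None = None,
    total_density: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[SedimentationSample]:
    """Simulate pellet/supernatant densitometry pairs for two nucleotide
    conditions.

    Per-replicate pellet fractions are Gaussian around the stated means,
    truncated to [0, 1]; densities are ``fraction * total_density`` and
    ``(1 - fraction) * total_density``.
    """
    for name, frac in (("fraction_gtp", fraction_gtp), ("fraction_gdp", fraction_gdp)):
        if not 0 <= frac <= 1:
            raise InvalidArgumentError(f"{name} must be in [0, 1]")
    if n < 2:
        raise InvalidArgumentError("need n >= 2 replicates per condition")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = []
    for nucleotide, mean in (("GTP", fraction_gtp), ("GDP", fraction_gdp)):
        fracs = np.clip(rng.normal(mean, noise_sd, n), 0.0, 1.0)
        for i, f in enumerate(fracs):
            samples.append(
                SedimentationSample(
                    label=f"sim-{nucleotide}-{i + 1}",
                    nucleotide=nucleotide,
                    density_supernatant=(1.0 - f) * total_density,
                    density_pellet=f * total_density,
                    density_total=total_density,
                )
            )
    return samples
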