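"""Metrics from 90-degree light-scattering (LS) assembly traces.

The LS signal reflects both polymerization and bundling, so all metrics
stay in arbitrary units: baseline, amplitude, the initial rate of
assembly, and — when the trace turns over and keeps falling — the onset
time of disassembly, which is then classified against the predicted GTP
depletion time for the same reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .depletion import DepletionPrediction
from .errors import InsufficientDataError, InvalidArgumentError

OnsetClass = Literal["before", "after", "no_disassembly", "no_prediction"]

MIN_SAMPLES_FOR_METRICS = 20


@dataclass(frozen=True)
class LSTrace:
    """One light-scattering trace.

    ``time`` is in seconds with nucleotide addition at t = 0 (baseline
    samples have negative times); ``intensity`` is in arbitrary units.
    ``meta`` carries labels and, for synthetic traces, ground truth.
    """

    time: np.ndarray
    intensity: np.ndarray
    nucleotide: str = "GTP"
    label: str = ""
    meta: dict = field(default_factory=dict)
    normalized: bool = False
    baseline: float | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or time.shape != intensity.shape:
            raise InvalidArgumentError("time and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")


@dataclass(frozen=True)
class LSMetrics:
    """Summary metrics for one LS trace."""

    baseline: float
    amplitude: float
    initial_rate: float
    rate_window: tuple[float, float] | None
    onset_time: float | None
    onset_vs_depletion: OnsetClass | None = None
    label: str = ""
    no_assembly: bool = False


def normalize_trace(trace: LSTrace, baseline_window: tuple[float, float] | None = None) -> LSTrace:
    """Subtract the pre-addition baseline mean and store it.

    ``baseline_window`` is (t0, t1) in seconds and must precede the
    nucleotide addition (t <= 0) and contain >= 3 samples; by default
    every sample with t < 0 is used. If no pre-addition samples exist the
    first 3 samples serve as baseline.
    """
    t, y = trace.time, trace.intensity
    if baseline_window is not None:
        lo, hi = baseline_window
        if hi > 0:
            raise InvalidArgumentError("baseline window must precede nucleotide addition (t <= 0)")
        mask = (t >= lo) & (t <= hi)
    else:
        mask = t < 0
        if not mask.any():
            mask = np.zeros_like(t, dtype=bool)
            mask[:3] = True
    if mask.sum() < 3:
        raise InvalidArgumentError("baseline window must contain >= 3 points")
    baseline = float(y[mask].mean())
    return replace(trace, intensity=y - baseline, normalized=True, baseline=baseline)


def _require_metric_ready(trace: LSTrace) -> None:
    if trace.time.size < MIN_SAMPLES_FOR_METRICS:
        raise InsufficientDataError(
            f"metric extraction needs >= {MIN_SAMPLES_FOR_METRICS} samples"
        )
    if not trace.normalized:
        raise InvalidArgumentError("trace must be normalized first (normalize_trace)")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the partial window."""
    if window <= 1:
        return y
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def amplitude(trace: LSTrace, smooth_window: int = 5) -> float:
    """Peak of the smoothed, baseline-subtracted signal (a.u., >= 0)."""
    _require_metric_ready(trace)
    post = trace.time >= 0
    return max(0.0, float(_smooth(trace.intensity, smooth_window)[post].max()))


def initial_rate(
    trace: LSTrace,
    fit_fraction: float = 0.5,
    noise_floor: float | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Initial assembly rate (a.u. s^-1) of a normalized trace.

    Fits a least-squares line to the earliest post-addition points, from
    signal start (t = 0) until the smoothed trace first reaches
    ``fit_fraction`` of its maximum (the line itself is fitted to the
    raw samples), and returns (slope, (t_start, t_end)). When the peak
    amplitude does not clear ``noise_floor``
    (default: 5x the pre-addition standard deviation, or 0 when no
    baseline samples exist) the trace is flagged no-assembly and
    (0.0, None) is returned.
    """
    _require_metric_ready(trace)
    if not 0 < fit_fraction <= 1:
        raise InvalidArgumentError("fit_fraction must be in (0, 1]")
    t, y = trace.time, trace.intensity
    pre = t < 0
    if noise_floor is None:
        noise_floor = 5.0 * float(y[pre].std()) if pre.sum() >= 3 else 0.0
    post = t >= 0
    tp, yp_raw = t[post], y[post]
    yp = _smooth(y, 5)[post]
    peak = float(yp.max())
    if peak <= noise_floor or peak <= 0:
        return 0.0, None
    stop = int(np.argmax(yp >= fit_fraction * peak))
    stop = max(stop, 2)  # need >= 3 points for a line
    slope = float(np.polyfit(tp[: stop + 1], yp_raw[: stop + 1], 1)[0])
    return slope, (float(tp[0]), float(tp[stop]))


def detect_onset(
    trace: LSTrace, smooth_window: int = 5, drop_fraction: float = 0.1
) -> float | None:
    """Time (s) at which disassembly begins, or None.

    The onset is the time of the smoothed trace's maximum, accepted only
    if the smoothed trace afterwards falls below
    ``(1 - drop_fraction) * max`` and stays below for at least
    ``smooth_window`` consecutive samples — a sustained drop, so noise
    spikes and brief dips never fire.
    """
    _require_metric_ready(trace)
    if not 0 < drop_fraction < 1:
        raise InvalidArgumentError("drop_fraction must be in (0, 1)")
    t, y = trace.time, trace.intensity
    post = t >= 0
    tp = t[post]
    yp = _smooth(y, smooth_window)[post]
    peak_idx = int(np.argmax(yp))
    peak = yp[peak_idx]
    if peak <= 0:
        return None
    below = yp[peak_idx + 1 :] < (1.0 - drop_fraction) * peak
    if below.size == 0:
        return None
    # longest run of consecutive below-threshold samples
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= smooth_window:
            return float(tp[peak_idx])
    return None


def classify_onset(
    metrics: LSMetrics, prediction: DepletionPrediction | None
) -> OnsetClass:
    """Classify disassembly onset relative to predicted GTP depletion.

    Raises :class:`InvalidArgumentError` if both carry nonempty labels
    that disagree (a guard against pairing metrics with the wrong
    reaction).
    """
    if (
        prediction is not None
        and metrics.label
        and prediction.label
        and metrics.label != prediction.label
    ):
        raise InvalidArgumentError(
            f"metrics label {metrics.label!r} != prediction label {prediction.label!r}"
        )
    if prediction is None or not prediction.defined:
        return "no_prediction"
    if metrics.onset_time is None:
        return "no_disassembly"
    assert prediction.depletion_time_s is not None
    return "before" if metrics.onset_time < prediction.depletion_time_s else "after"


def analyze_trace(
    trace: LSTrace,
    prediction: DepletionPrediction | None = None,
    fit_fraction: float = 0.5,
    smooth_window: int = 5,
    drop_fraction: float = 0.1,
    noise_floor: float | None = None,
) -> LSMetrics:
    """Full metric extraction for one trace: normalize if needed, then
    amplitude, initial rate, onset detection and classification."""
    if not trace.normalized:
        trace = normalize_trace(trace)
    amp = amplitude(trace, smooth_window)
    rate, window = initial_rate(trace, fit_fraction, noise_floor)
    onset = detect_onset(trace, smooth_window, drop_fraction) if window is not None else None
    metrics = LSMetrics(
        baseline=trace.baseline if trace.baseline is not None else 0.0,
        amplitude=amp,
        initial_rate=rate,
        rate_window=window,
        onset_time=onset,
        label=trace.label,
        no_assembly=window is None,
    )
    return replace(metrics, onset_vs_depletion=classify_onset(metrics, prediction))
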