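# Methods

## GTPase kinetics from the coupled assay

The regenerative assay couples each GTP hydrolysis to oxidation of one
NADH, so absorbance at 340 nm declines linearly while hydrolysis is at
steady state. `velocity_from_trace` fits an OLS line to A340 vs time
over a configurable window and converts the slope through Beer–Lambert:

    v (μM/min) = max(0, −dA/dt · 60) / (ε · ℓ) · 10⁶

with NADH extinction coefficient ε = 6220 M⁻¹cm⁻¹ and effective path
length ℓ = 0.56 cm by default (a 200 μl reaction in a 96-well plate,
read top-down; both are exposed because the conversion depends on them
and plate geometry varies). Velocities are clamped at zero — the
coupled assay cannot report negative hydrolysis — and expressed in
μM/min throughout.

`fit_kinetics` regresses velocity on FtsZ concentration over the linear
range, defined by default as all points with velocity > 0; an explicit
concentration-range override exists because range choices differ
between assays. Activity is the slope; the critical concentration is
the x-intercept Cc = −b/a, with its standard error from the
slope/intercept covariance by the delta method
(∇Cc = (b/a², −1/a)). Replicate assays are fitted independently and
pooled by `pool_replicate_fits` (mean ± between-assay SD), matching how
kinetic parameters are conventionally reported for this assay.
Mixtures use the same regression against total FtsZ via
`mixture_activity`, which exists purely to enforce that convention.

## GTP depletion model

Two closed-form quantities per reaction:

    adjusted (μM)      = total FtsZ (μM) − Cc (μM),   floored at 0
    depletion time (s) = GTP (μM) / (adjusted × activity) × 60

The model assumes hydrolysis proceeds at the fitted per-enzyme rate for
every subunit above Cc until the pool is exhausted; product inhibition
and time-resolved nucleotide exchange are out of scope. Reported times
are truncated (floored) to whole seconds; with activity 0.59, Cc 2.12
and 50 μM GTP this yields 428 s at 14 μM (raw 428.01) and 2704 s at
4 μM (raw 2704.65). Truncation rather than rounding is the convention
consistent with both of those worked values (rounding would give 2705);
since it is inferred from only two values it is exposed as a
`rounding` toggle. Reactions at or below Cc raise an
undefined-prediction signal from `depletion_time` (no polymer, no
hydrolysis); the batch-friendly `predict` returns an undefined-flagged
record instead so concentration series stay computable.

## Light-scattering metrics

The 90° LS signal reflects both polymerization and bundling, so all
metrics stay in arbitrary units; no conversion to polymer mass is
attempted.

- **Normalization** subtracts the mean of the pre-addition baseline
  (samples with t < 0 by default, or an explicit window) and stores it.
- **Initial rate**: OLS slope over the earliest post-addition samples,
  from t = 0 until the smoothed trace first reaches `fit_fraction`
  (default 0.5) of its maximum. The crossing is located on a smoothed
  copy (centered moving average, window 5) but the line is fitted to
  the raw samples, so a noiseless linear rise returns its slope
  exactly. Window endpoints are recorded for transparency, since the
  exact window used when reading rates off published traces is
  generally unstated. Traces whose peak does not clear a noise floor
  (default 5× the baseline SD) return rate 0 with a no-assembly flag.
- **Disassembly onset**: the time of the smoothed trace's maximum,
  accepted only if the smoothed signal subsequently falls below
  (1 − `drop_fraction`)·max (default 0.1) and stays below for at least
  `smooth_window` consecutive samples. The sustained-drop criterion
  keeps the detector from firing on noise spikes or brief dips, and it
  provably never fires on monotone traces. The rule is deliberately
  explicit and configurable because onsets are otherwise read
  qualitatively off traces.
- **Classification**: onset < predicted depletion time → `before`,
  otherwise `after`; no onset → `no_disassembly`; undefined prediction
  (reaction at or below Cc) → `no_prediction`.

A known property of the argmax-based onset detector: a centered moving
average shifts the apparent peak of an asymmetric corner toward its
shallower side by up to half the window, and when disassembly starts
from a long flat plateau the argmax under noise is distributed across
the plateau rather than at its end. Onset estimation is therefore only
sample-accurate when the trace turns over while still rising — the
regime the synthetic batch below emulates — and that is a genuine
limitation for slowly-assembling traces with late onsets.

## FRAP

Raw bleach/reference/background region intensities are
double-normalized: background is subtracted from bleach and reference
at each frame, the bleach/reference ratio corrects acquisition
photobleaching and drift, and division by the prebleach mean of that
ratio puts the curve on a 0–1 scale. The exact arithmetic of the
correction is a design choice here (the conventional double
normalization); any common offset in all three channels cancels.

The two-binding-state reaction-dominant model

    FRAP(t) = (1 − r)(1 − C_eq1 e^(−koff1 t) − C_eq2 e^(−koff2 t))

is fitted to postbleach frames (t = 0 at the first postbleach frame;
the ~20 ms bleach is treated as instantaneous relative to 10 s
sampling) by bounded trust-region least squares with multistart
(default 20 starts: one heuristic start from the curve shape plus
seeded random draws). Rates are optimized in log space within
[10⁻⁶, 10] s⁻¹; the simplex constraint C_eq1 + C_eq2 ≤ 1 is enforced
exactly by parametrizing (total bound fraction, split fraction), which
box bounds alone cannot express. The lowest-RSS solution is kept,
koff1 ≥ koff2 is enforced by relabeling, parameters at bounds are
flagged, and the maximum absolute residual is reported so fits can be
checked against the convention that all data points should lie within
0.05 normalized units of the curve. When koff1/koff2 < 2 at the
optimum the two rates are not separately identifiable and a reduced
single-state fit is reported alongside.

Identifiability caveat: with 31 frames at 10 s the slow decay of a
koff2 ≈ 0.005 s⁻¹ state spans only ~1.5 time constants, so the plateau
(hence percent recovery) carries a few-percentage-point statistical
uncertainty at noise SD 0.01, and rate constants are only reliably
recovered within 20% when both decays are resolved by the window
(koff2 ≳ 0.01 s⁻¹) and noise is ≲ 0.01. The property tests use those
conditions; at noise SD 0.02 the slow rate is simply not identifiable
from a 300 s record, regardless of optimizer.

## Sedimentation statistics

Pellet fraction = pellet / (pellet + supernatant) from densitometry;
the uncentrifuged total lane is recorded for QC only (a warning fires
when |pellet + supernatant − total| / total > 0.25) because the
fraction's definition uses only the two centrifuged fractions.
Conditions are compared with a two-sided unpaired t test — Student
(equal variance) by default since nothing more specific is conventional
for n = 3 densitometry replicates, with Welch behind a flag, and the
two-sidedness noted in output. Groups with exactly zero within-group
variance (possible with noise-free synthetic data) are handled by an
epsilon guard: identical groups give t = 0, p = 1; perfectly separated
ones give a finite, astronomically significant t.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seeded `numpy.random.Generator` (derived
from `GroundTruth.seed` unless passed explicitly); identical seeds give
bit-identical outputs. Defaults are the study-like conditions: activity
0.59 GTP min⁻¹ FtsZ⁻¹, Cc 2.12 μM, protein series 2–14 μM, 50 μM GTP,
FRAP sampling of 3 prebleach + 30 postbleach frames at 10 s.

- **GTPase traces**: exactly linear A340 decline with slope
  −v·ε·ℓ·10⁻⁶ per minute plus additive Gaussian noise (SD 0.002
  absorbance units, a typical plate-reader floor), clipped at zero.
  No coupled-enzyme lag, no substrate-depletion curvature.
- **LS traces**: saturating-exponential rise A(1 − e^(−kt)) with
  amplitude linear in (C − Cc) above Cc (10 a.u./μM) and rise rate
  0.05 s⁻¹ (tens-of-seconds assembly, i.e. rapid), zero-mean noise
  below Cc; optional decay from a set onset, linear at
  `decay_rate`·A per second (default 0.002; exponential optional).
  Additive Gaussian noise, default SD 1 a.u. (~1–2% of a mid-range
  amplitude) — instrument noise for this class of fluorimeter is not
  standardized, so the level is configurable. Real LS traces also show
  bundling-driven slow drift and multiplicative noise; none of that is
  modeled, so passing recovery tests demonstrate correctness of the
  metric definitions, not robustness to every real-trace pathology.
- **FRAP traces**: bleach ROI at bg + (pre − bg)·FRAP(t), constant
  reference and background channels, Gaussian noise of SD
  `noise_frap`·(pre − bg) so the noise is `noise_frap` in normalized
  units. No acquisition photobleaching (the reference channel is flat),
  no diffusion component.
- **Sedimentation**: per-replicate pellet fractions Gaussian around the
  stated condition means, truncated to [0, 1].

The onset-recovery test batch places onsets 20–60 s into the rise with
decay 0.01·A s⁻¹ at 2 s sampling: disassembly beginning while assembly
is still decelerating produces the rounded, genuinely located peak that
the highest-concentration traces show, and is the regime where an
argmax detector is meaningfully testable (see the LS caveat above).
Problem sizes throughout the suite — 200 regression replicates, 100
FRAP fits, 100 LS traces — are chosen to estimate recovery rates with
a few-percent margin while keeping the full suite under a minute of
fitting time.

## Known limitations

- The depletion model ignores GDP accumulation and product inhibition;
  it predicts pool exhaustion, not the observed disassembly onset
  (empirically earlier for cyanobacterial-type protofilaments).
- Onset detection is argmax-based and not reliable for late onsets
  after long plateaus (documented above).
- The FRAP model is reaction-dominant; diffusion-coupled recovery and
  ROI extraction from images are out of scope.
- Co-sedimented species cannot be resolved per protein; fractions are
  per-lane totals.
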