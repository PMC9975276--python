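# ftszdyn

Quantitative analysis of FtsZ protofilament assembly dynamics in vitro.

FtsZ is the tubulin-homolog GTPase that polymerizes into single-stranded
protofilaments and forms the contractile "Z ring" at bacterial and
chloroplast division sites. Its in-vitro characterization rests on a
small set of standard measurements — a regenerative NADH-coupled GTPase
assay, 90° light scattering (LS), sedimentation, and FRAP of assembled
structures in living cells — and on a closed-form prediction of when the
GTP pool in an assembly reaction runs out. `ftszdyn` implements that
analysis chain as a tested, reusable library with a thin CLI, plus a
seeded synthetic-data generator so every stage has a parameter-recovery
test surface.

## What it computes

**GTPase kinetics** (`ftszdyn.gtpase`). In the coupled assay, pyruvate
kinase regenerates GTP while lactate dehydrogenase oxidizes NADH 1:1, so
the A340 decline reports the steady-state hydrolysis velocity. Because
GTP hydrolysis requires oligomerization, velocity is linear in FtsZ
concentration above a critical concentration *C<sub>c</sub>* and zero
below. An OLS line through the active points gives

- GTPase activity *a* = slope (GTP min⁻¹ FtsZ⁻¹),
- *C<sub>c</sub>* = x-intercept (μM), with its standard error by the
  delta method.

For coassembled mixtures, `mixture_activity` enforces the convention
that velocities are regressed against **total** FtsZ concentration.

**GTP depletion prediction** (`ftszdyn.depletion`):

```
adjusted (μM)     = total FtsZ (μM) − Cc (μM)
depletion time (s) = GTP (μM) / (adjusted × a) × 60
```

**Light scattering** (`ftszdyn.lightscattering`). Baseline-subtracted
amplitude, initial assembly rate (slope from signal start to half-max by
default), disassembly onset (smoothed argmax subject to a sustained-drop
criterion), and classification of the onset as before/after the
predicted depletion time.

**FRAP** (`ftszdyn.frap`). Double normalization of bleach / reference /
background region traces, then a multistart bounded least-squares fit of
the two-binding-state recovery model

```
FRAP(t) = (1 − r)(1 − C_eq1 e^(−koff1 t) − C_eq2 e^(−koff2 t))
```

yielding dissociation rate constants, bound fractions, and percent
recovery 100·(1 − r).

**Sedimentation** (`ftszdyn.sedimentation`). Pellet fractions
`pellet / (pellet + supernatant)` from densitometry, and a two-sided
unpaired t test between nucleotide conditions (Student by default,
Welch by flag).

## Worked example

Simulate a coupled-assay series (activity 0.59 GTP min⁻¹ FtsZ⁻¹,
*C<sub>c</sub>* 2.12 μM, 2–14 μM protein), refit it, and predict
depletion times for 50 μM GTP:

```
$ echo '{"seed": 7, "noise_a340": 0.002}' > cfg.json
$ ftszdyn simulate --config cfg.json --out-dir . --kind gtpase
$ ftszdyn gtpase gtpase_traces.csv
activity = 0.593 +/- 0.002 GTP min^-1 FtsZ^-1; Cc = 2.16 +/- 0.026 uM (n=6, R^2=1.0000)
```

The fitted slope and x-intercept recover the generator's ground truth to
within the noise-limited uncertainty. Feeding the published kinetic
parameters into the depletion model:

```
$ printf 'label,total_uM,gtp_uM,activity,cc\nSeFtsZ-14,14,50,0.59,2.12\nSeFtsZ-4,4,50,0.59,2.12\nSeFtsZ-2,2,50,0.59,2.12\n' > rx.csv
$ ftszdyn deplete rx.csv
    label  total_uM  adjusted_uM  depletion_s
SeFtsZ-14      14.0        11.88          428
 SeFtsZ-4       4.0         1.88         2704
 SeFtsZ-2       2.0         0.00         <NA>
```

At 14 μM the 50 μM GTP pool is predicted to last 428 s; at 4 μM,
2704 s; at 2 μM — below *C<sub>c</sub>* — no polymer forms, so no
hydrolysis occurs and the prediction is undefined. The same library
calls are available in Python:

```python
import ftszdyn as fz

gt = fz.GroundTruth(seed=7, noise_frap=0.01)           # 95% recovery truth
rec = fz.normalize_frap(fz.make_frap_trace(gt))
fit = fz.fit_frap(rec, seed=7)
print(f"recovery {fit.recovery_percent:.1f}%  koff1 {fit.koff1:.4f} s^-1")
# recovery 100.0%  koff1 0.0477 s^-1
```

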