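# Methods

## The system being modelled

The package models the software half of an ex situ PV-loop platform: a
saline-filled balloon in the vented left ventricle is coupled through a
mitral cannula to a motor-driven piston–cylinder, forming a fluid-tight
system with a constant, preset total volume. A pressure catheter in the
balloon and the piston position give per-sample pressure and volume. The
supervisor recomputes its target at every control step `dt` (bounded at
4 ms) and, depending on the detected cardiac phase, regulates preload,
holds the piston, or imposes the virtual afterload.

All pressures at module boundaries are mmHg; flows are cm³/s and volumes
cm³. The impedance components are specified in cgs (Barye-based) units and
converted with 1 mmHg = 1333.22 Barye exactly where flow×resistance or
inertance×flow-derivative products meet a pressure. Clinical convention
quotes flow in mL/min, which is dimensionally inconsistent with
Barye·s/cm³ resistances; the package uses cm³/s (= mL/s) throughout and
treats mL/min as an I/O-boundary display concern.

## Virtual afterload

During ejection the target pressure is
`P = L·dQ/dt + Q·Rp + Pc`, where `Pc` is the compliance pressure — the
realized value of `(1/C)∫(Q − Q_Rd)dt + P_C0` carried as a continuous state
across beats rather than re-zeroed, with `P_C0 := Pc` latched at each
ejection onset. The distal runoff is closed as `Q_Rd = Pc/Rd`, the standard
Windkessel reading of the circuit analogue; it is the only closure that
reproduces the published closed-form discharge `Pc(t) = Pces·e^{−t/(Rd·C)}`
when `Q = 0`. That closed form is kept in the API (`decay_pressure`) as the
analytic oracle for the numerical state update.

`step_compliance` advances `dPc/dt = (Q − Pc/Rd)/C` with one classical
4th-order Runge–Kutta step per control step. At the standard time constant
(`Rd·C = 404.6/420 ≈ 0.963 s`) and `dt ≤ 4 ms` the truncation error is near
machine precision; the convergence-order test therefore uses a deliberately
stiff RC (`Rd·C = 20 ms`) so that halving `dt` shows the formal 16× error
contraction above floating-point rounding.

Component defaults are the device standard settings: `L = 0.7 Barye·s²/cm³`,
`1/C = 420 Barye/cm³`, `Rp = 24.5 Barye·s/cm³`, `Rd = 404.6 Barye·s/cm³`.
Note the scale: `Rd = 404.6 Barye·s/cm³ ≈ 0.30 mmHg·s/mL`, several-fold
below a physiologic systemic vascular resistance. At an ovine-scale cardiac
output the virtual aorta therefore equilibrates near 10–20 mmHg and the
simulated loops run at correspondingly modest pressures. This is a property
of the standard settings, not of the implementation; the parameters are
fully configurable.

## Phase detection

The four rules are applied in cycle order with at most one transition per
control step, which guarantees that the label sequence can only walk
1→2→3→4→1 regardless of input. The displacement thresholds default to
`eps_out = eps_in = 0.1 cm³` per step — about 0.3% of an ovine stroke
volume, far above simulated sensor-induced piston jitter — and are
configurable independently (whether the physical device shares one ε is not
documented). `dV` is the displacement over a single control step, matching
the real-time framing of the detector.

## Controller

The device regulates pressure by modulating motor power; no motor physics
are published. The package uses the simplest scheme that honors every
stated contract:

- **Filling** — a proportional pressure regulator,
  `Q = motor_gain·(P_lv − setpoint)` (positive = out of the ventricle),
  default gain 50 cm³/(s·mmHg). The regulator is deliberately
  *bidirectional*: it injects while the ventricle is below the setpoint and
  yields once contraction drives pressure above it. An injection-only
  piston could never produce the outward displacement that the detector
  needs to mark the start of isovolumetric contraction — in a fluid-tight
  system volume moves only with the piston — so bidirectionality is
  required by the phase-detection rule itself.
- **Isovolumetric phases** — `Q = 0` held exactly (no servo jitter).
- **Ejection** — the outflow evolves through the inertance,
  `dQ/dt = (P_lv − Q·Rp − Pc)/L`, advanced per step by the exact
  exponential update of this linear ODE with the sampled pressures held
  over the step (zero-order hold, as a discrete controller would). This
  integration closes the algebraic loop between the measured ventricular
  pressure and the afterload equation.

Balloon and cylinder volumes are updated with the same displacement each
step, so their sum is conserved to rounding (the suite asserts < 1e−9 cm³
over a full protocol). Preload setpoint changes are latched and applied
only at the next filling-phase entry, never mid-beat. Preload is regulated
as a constant filling-pressure target (consistent with the
relaxation→filling rule, which compares against "the preload pressure"),
not as an end-diastolic-pressure target.

The ramp protocol defaults to 10 → 25 mmHg in 5 mmHg steps. The recording
dwell per level defaults to 60 s as in the assessment protocol; package
test runs and the acceptance script use 5 s, since at a paced, noise-free
steady state additional beats are identical. Before recording, the loop
runs a discarded 8 s warmup at the first level so the virtual aorta reaches
its periodic steady state — the analogue of the heart beating on the device
before a recording is started. Analysis additionally discards 2 settling
beats at the start of each level (the beat-to-beat compliance-pressure map
contracts by ~e^{−T_diastole/RdC} ≈ 0.6 per beat, so two beats remove most
of a level-change transient).

## Synthetic ventricle

`P(V,t) = a(t)·Ees·(V − V0) + (1 − a(t))·A·(e^{B(V−V0)} − 1)` with a
double-Hill activation (rising Hill exponent 1.9, falling exponent 21.9,
half-times 0.269·T and 0.452·T) normalized to peak 1, putting systole near
35% of the cycle at the default 70 beats/min pacing. Defaults:
`Ees = 2.7 mmHg/mL` (within the range reported for healthy ovine hearts),
`V0 = 10 mL`, passive constants `A = 1 mmHg`, `B = 0.05 /mL` — plausible
adult-ovine placeholders; no published ovine passive-curve constants back
them, and nothing in the analysis depends on their exact values. Gaussian
sensor noise (default off) is added to the *measured* pressure only; volume
is piston-derived and treated as exact, as in the physical system.

What the generator emulates: Frank–Starling loop growth with preload,
isovolumic pressure rise/fall, ejection against the virtual impedance,
pacing. What it does not: arrhythmia and ectopy, valve regurgitation,
balloon–wall interaction, catheter drift, motor/Bowden-cable friction, and
ischemic time-dependence of contractility. Passing recovery tests therefore
show that the *pipeline* is unbiased under ideal mechanics, not that the
device is accurate on a real heart.

## End-systolic point definition

The device's own phase boundary (ejection → isovolumetric relaxation) is
detected only after the inward-displacement hysteresis `eps_in` is exceeded
through the inertance — measured on the closed loop this happens ~40 ms
after peak activation, when activation has already fallen to ~0.6, so the
transition sample sits well off the end-systolic elastance line and biases
the fitted slope by several percent. The primary end-systolic definition is
therefore a **maximal-elastance search**: per beat, the ejection sample
maximizing `P/(V − V0_fit)`, where `V0_fit` comes from the ESPVR fit itself
and is iterated to convergence (initialized from the last forward-flow
sample, i.e. aortic-valve closure; typically 2–3 iterations). This uses
only observable quantities. The raw phase-transition sample remains
available (`es_method="phase"`) for sensitivity analysis, as does the
valve-closure sample (`es_method="reversal"`).

Multiple beats per level are averaged per level before the ESPVR
least-squares fit, matching the record-then-average design of the
assessment protocol. The across-level OLS fit is the primary Ees estimator
(the protocol is explicitly a preload ramp); no single-beat method is
implemented.

## Tau and dP/dt

Tau uses the Weiss convention: a log-linear fit of
`P(t) = P_a·e^{−t/τ}` on the window from the time of dP/dt_min to the end
of the isovolumetric-relaxation segment; the Glantz variant with a free
asymptote is available (`tau_method="glantz"`). Windows shorter than 5
samples, non-decaying or constant windows are flagged rather than fitted —
with the light standard afterload, end-ejection pressure at higher preload
levels can fall below the setpoint within a few samples, which makes the
relaxation segment legitimately too short for a fit; the metric is then
NaN with a flag rather than a fabricated number. dP/dt uses central
differences (`numpy.gradient`); optional smoothing is deliberately absent
by default so that reported extrema are raw.

## Degenerate inputs and numerical edge cases

- `step_compliance` and the controller reject `dt` outside (0, 4 ms].
- Negative outflow during ejection and non-finite samples are rejected at
  the afterload interface; non-finite closed-loop state aborts with the
  preload level and beat index.
- The EDPVR exponential `P = A·(e^{B(V−V_ref)} − 1)` is fitted with `V_ref`
  free (with it fixed, the form cannot absorb any pressure offset and
  degenerates); `A, B` are bounded positive. Model form is chosen by AIC
  against a straight line, with a warned linear fallback on
  non-convergence. Exactly collinear input selects the linear form.
- The ESPVR fit refuses fewer than two distinct preload levels and
  zero volume variance.

## Known limitations

- The motor is abstracted to a proportional flow law; gain is a tuning
  parameter (default 50 cm³/(s·mmHg)), not derived from hardware.
- Decreasing-preload steps can transiently mislabel one filling phase as
  isovolumetric contraction (the withdrawal itself is an outward
  displacement); the standard protocol only increases preload.
- The end-diastolic point is taken at the filling→contraction transition,
  which includes the pressure rise needed to trip the displacement
  detector (~2 mmHg above the setpoint at default gain and `dt`); EDPVR
  fits inherit this offset, which `V_ref` absorbs.
- Tau from closed-loop traces reflects the activation waveform's relaxation
  limb, not an independently programmed constant; only the pure-exponential
  recovery tests have ground truth.
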