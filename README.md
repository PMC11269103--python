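# pvloop

Software model and analysis suite for **ex situ left-ventricular
pressure–volume (PV) loop assessment** during machine perfusion of donor
hearts.

During ex situ heart perfusion (ESHP) the coronary arteries are perfused but
the ventricles are unloaded, so contractile function cannot be judged from
the usual loaded indices. A PV-loop platform solves this with a fluid-filled
intraventricular balloon coupled to a motor-driven piston: the piston imposes
a *virtual preload* (an adjustable filling pressure) and a *virtual
afterload* (a lumped arterial impedance), so the vented ventricle performs
real pressure–volume work and load-independent contractility indices become
measurable. `pvloop` implements every software component of such a platform —
the virtual impedance, the cardiac-phase detector, the preload-challenge
controller, and the metric suite — closed against a synthetic
time-varying-elastance ventricle that provides known ground truth, so the
entire pipeline is testable without hardware or animal data.

## Model

**Virtual afterload.** During systolic ejection the target ventricular
pressure is computed from the measured outflow `Q` through a simplified
four-component Windkessel (inertance `L`, proximal/aortic-valve resistance
`Rp`, compliance `C`, distal/SVR resistance `Rd`):

    P = L·dQ/dt + Q·Rp + (1/C)·∫(Q − Q_Rd) dt + P_C0

with `Q_Rd = Pc/Rd` the distal runoff and `P_C0` the aortic pressure at
ejection onset. Outside ejection the virtual aortic valve is closed and the
compliance pressure relaxes along the RC discharge
`Pc(t) = Pces·exp(−t/(Rd·C))`. Component defaults are the device standard
settings (`L = 0.7 Barye·s²/cm³`, `1/C = 420 Barye/cm³`,
`Rp = 24.5`, `Rd = 404.6 Barye·s/cm³`; 1 mmHg = 1333.22 Barye).

**Phase detection.** Each control step (dt ≤ 4 ms) is labeled diastolic
filling → isovolumetric contraction → ejection → isovolumetric relaxation by
four rules: outward volume displacement, threshold pressure (the current
virtual aortic pressure), inward volume displacement, and pressure falling
below the preload setpoint. Transitions are evaluated in cycle order, at
most one per step.

**Assessment protocol and metrics.** A stepped preload challenge
(10 → 25 mmHg in 5 mmHg increments at 70 beats/min pacing) yields loops at
four filling pressures. Per beat the suite reports dP/dt max/min, maximal
pressure, end-diastolic and end-systolic points, stroke work and the
isovolumic-relaxation constant Tau (Weiss, optionally Glantz); across the
ramp it fits the end-systolic pressure–volume relationship
`P = Ees·(V − V0)` (Ees = end-systolic elastance, the contractility index)
and the end-diastolic relationship (EDPVR, exponential with linear
fallback).

**Synthetic ventricle.** A time-varying elastance model
`P = a(t)·Ees·(V − V0) + (1 − a(t))·A·(e^{B(V−V0)} − 1)` with a double-Hill
activation `a(t)` closes the loop and defines the ground truth the analysis
must recover.

## Worked example

```bash
pvloop simulate --dwell 5 --seed 1 --out trace.csv
pvloop analyze --trace trace.csv --report report.json
```

prints

```
wrote 20000 samples across levels [10.0, 15.0, 20.0, 25.0] to trace.csv
Ees = 2.700 mmHg/mL (V0 = 10.00 mL, r2 = 1.0000) over levels [10.0, 15.0, 20.0, 25.0]; report -> report.json
```

The simulated heart was programmed with `Ees_true = 2.7 mmHg/mL` (the
default), and the ESPVR regression over the four preload levels recovers
slope 2.700 mmHg/mL with volume intercept 10.00 mL (the programmed
unstressed volume) and r² = 1.0000 — the load-independent contractility
index is read back from waveforms alone. `report.json` holds the per-beat
metrics with units; for the first analyzed beat of this run:
dP/dt max/min = 226/−314 mmHg/s, peak pressure 22.2 mmHg,
EDV 57.1 mL, ESV 16.3 mL, stroke volume 40.8 mL, stroke work
583 mmHg·mL, Tau ≈ 34.5 ms. (Pressures are modest because the standard
distal resistance is deliberately light; see `docs/methods.md`.)

The same end-to-end run is available as one command:
`pvloop protocol --dwell 5 --seed 1 --report report.json`.

## Layout

| module | role |
| --- | --- |
| `pvloop.impedance` | Windkessel afterload equation, compliance state, RC decay |
| `pvloop.phases` | four-phase cardiac-cycle detector |
| `pvloop.controller` | preload regulation, ejection flow dynamics, ramp protocol |
| `pvloop.heart` | synthetic time-varying-elastance ventricle |
| `pvloop.analysis` | beat segmentation, loop metrics, ESPVR/EDPVR/Tau fits |
| `pvloop.trace`, `pvloop.io`, `pvloop.cli` | trace/report/config I/O and CLI |

Methods, parameter choices and known limitations: `docs/methods.md`.
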