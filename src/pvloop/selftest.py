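"""Built-in analytic-oracle checks, runnable from the CLI (`pvloop selftest`).

Each check compares a numerical path against an independent closed form:
the RC discharge of the compliance, the exponential-decay time-constant
fit, and central-difference dP/dt extrema on a sinusoid.
"""

from __future__ import annotations

import math

import numpy as np

from .analysis import fit_exponential_decay
from .impedance import AfterloadState, ImpedanceParams, decay_pressure, step_compliance


def run_selftest() -> list[str]:
    """Run all checks; return a list of failure descriptions (empty = pass)."""
    failures: list[str] = []

    # RC discharge: iterated RK4 vs closed form over five time constants.
    params = ImpedanceParams()
    dt = 0.002
    state = AfterloadState(Pc=80.0)
    t = 0.0
    worst = 0.0
    while t < 5 * params.tau_s:
        state = step_compliance(params, state, 0.0, dt)
        t += dt
        exact = decay_pressure(params, 80.0, t)
        if exact > 1e-12:
            worst = max(worst, abs(state.Pc - exact) / exact)
    if worst > 1e-3:
        failures.append(f"RC-decay oracle: max relative error {worst:.2e} > 1e-3")

    # Tau fit on a pure exponential.
    tt = np.arange(0, 0.2, 0.001)
    for tau_ms in (20.0, 40.0, 60.0):
        p = 80.0 * np.exp(-tt / (tau_ms / 1000.0))
        got = fit_exponential_decay(tt, p, method="weiss")
        if abs(got - tau_ms) / tau_ms > 1e-3:
            failures.append(f"tau fit: {got:.4f} ms vs {tau_ms} ms")

    # dP/dt extrema of A*sin(w*t) are +-A*w.
    A, f = 40.0, 1.0
    w = 2 * math.pi * f
    ts = np.arange(0, 2.0, 0.001)
    dpdt = np.gradient(A * np.sin(w * ts), ts)
    bound = A * w * (w * 0.001) ** 2  # central-difference truncation
    if abs(dpdt.max() - A * w) > 10 * bound or abs(dpdt.min() + A * w) > 10 * bound:
        failures.append(
            f"dP/dt extrema {dpdt.max():.3f}/{dpdt.min():.3f} vs +-{A * w:.3f}"
        )

    return failures
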