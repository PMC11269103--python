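"""Synthetic left ventricle: a time-varying elastance model.

Ground-truth generator for exercising the controller, impedance and
analysis code without hardware or animal data.  Instantaneous ventricular
pressure is

    P(V, t) = a(t) * Ees * (V - V0) + (1 - a(t)) * P_pass(V)

with ``a(t)`` a periodic activation waveform in [0, 1] (double-Hill shape,
paced at a fixed rate), ``Ees`` the end-systolic elastance, ``V0`` the
unstressed volume, and an exponential passive (end-diastolic) curve

    P_pass(V) = A * (exp(B * (V - V0)) - 1).

At peak activation (a = 1) the model collapses onto the end-systolic
pressure-volume line P = Ees*(V - V0); at rest (a = 0) onto the passive
curve.  Optional Gaussian sensor noise is added to the *measured* pressure
only — the underlying mechanics stay noise-free and volume is piston-derived
and exact, as in the physical system.

Default geometry (V0, A, B) is a plausible adult ovine ventricle; the
elastance default is in the range reported for healthy ovine hearts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .controller import ControllerConfig, RampProtocol
    from .trace import WaveformTrace


@dataclass(frozen=True)
class HeartParams:
    """Parameters of the synthetic time-varying elastance ventricle.

    Attributes
    ----------
    Ees_true : float
        End-systolic elastance, mmHg/cm^3 (the programmed ground truth
        recovered by ESPVR analysis).
    V0 : float
        Unstressed volume, cm^3.
    A, B : float
        Passive-curve constants, mmHg and 1/cm^3:
        P_pass = A*(exp(B*(V - V0)) - 1).
    hr : float
        Paced heart rate, beats/min.
    act_n1, act_n2 : float
        Hill exponents of the rising and falling limbs of the activation
        waveform; n2 >> n1 gives a rapid, switch-like relaxation.
    act_tau1_frac, act_tau2_frac : float
        Hill half-activation times as fractions of the cycle length.
        Defaults put systole at roughly 35% of the cycle at 70 beats/min.
    noise_sd : float
        Pressure-sensor noise standard deviation, mmHg.
    seed : int
        Seed for the sensor-noise stream.
    """

    Ees_true: float = 2.7
    V0: float = 10.0
    A: float = 1.0
    B: float = 0.05
    hr: float = 70.0
    act_n1: float = 1.9
    act_n2: float = 21.9
    act_tau1_frac: float = 0.269
    act_tau2_frac: float = 0.452
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.Ees_true > 0:
            raise ValueError("Ees_true must be > 0")
        if self.V0 < 0:
            raise ValueError("V0 must be >= 0")
        if self.A < 0 or self.B < 0:
            raise ValueError("passive-curve constants A and B must be >= 0")
        if not self.hr > 0:
            raise ValueError("heart rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def period_s(self) -> float:
        """Cycle length, s."""
        return 60.0 / self.hr


@lru_cache(maxsize=32)
def _activation_norm(n1: float, n2: float, tau1: float, tau2: float, T: float) -> float:
    """Peak of the un-normalized double-Hill product over one cycle."""
    t = np.linspace(0.0, T, 4001)
    g = _double_hill(t, n1, n2, tau1, tau2)
    return float(g.max())


def _double_hill(t, n1: float, n2: float, tau1: float, tau2: float):
    x1 = (t / tau1) ** n1
    rise = x1 / (1.0 + x1)
    fall = 1.0 / (1.0 + (t / tau2) ** n2)
    return rise * fall


def activation(params: HeartParams, t: float) -> float:
    """Activation a(t) in [0, 1], periodic with the pacing period."""
    T = params.period_s
    tau1 = params.act_tau1_frac * T
    tau2 = params.act_tau2_frac * T
    tc = math.fmod(t, T)
    norm = _activation_norm(params.act_n1, params.act_n2, tau1, tau2, T)
    a = float(_double_hill(tc, params.act_n1, params.act_n2, tau1, tau2)) / norm
    return min(max(a, 0.0), 1.0)


def passive_pressure(params: HeartParams, V: float) -> float:
    """Passive (end-diastolic) pressure at volume ``V``, mmHg."""
    return params.A * math.expm1(params.B * (V - params.V0))


def lv_pressure(
    params: HeartParams, V: float, t: float, rng: np.random.Generator | None = None
) -> float:
    """Left-ventricular pressure at volume ``V`` (cm^3) and time ``t`` (s).

    Deterministic given the seed: pass an ``rng`` (seeded from
    ``params.seed``) to add sensor noise; without one the model pressure is
    returned noise-free.
    """
    if V < 0:
        raise ValueError("ventricular volume must be >= 0")
    a = activation(params, t)
    p = a * params.Ees_true * (V - params.V0) + (1.0 - a) * passive_pressure(params, V)
    if rng is not None and params.noise_sd > 0:
        p += params.noise_sd * rng.standard_normal()
    return p


def ed_volume(params: HeartParams, p_ed: float) -> float:
    """Volume on the passive curve at filling pressure ``p_ed`` (mmHg)."""
    if params.A == 0 or params.B == 0:
        raise ValueError("passive curve is flat; end-diastolic volume undefined")
    return params.V0 + math.log(p_ed / params.A + 1.0) / params.B


def generate_trace(
    params: HeartParams,
    cfg: "ControllerConfig | None" = None,
    protocol: "RampProtocol | None" = None,
) -> "WaveformTrace":
    """Run the full closed-loop simulation and return the labeled trace.

    Convenience wrapper over :func:`pvloop.controller.run_protocol` that
    concatenates the per-level traces; reproducible given ``params.seed``.
    """
    from .controller import ControllerConfig, RampProtocol, run_protocol
    from .trace import concat_traces

    cfg = cfg if cfg is not None else ControllerConfig()
    protocol = protocol if protocol is not None else RampProtocol()
    return concat_traces(run_protocol(cfg, protocol, params))
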