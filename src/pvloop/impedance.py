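"""Virtual afterload: a four-component lumped arterial impedance.

The load the ventricle ejects against is a simplified Windkessel — an
inertance ``L``, a proximal (aortic-valve) resistance ``Rp``, an arterial
compliance ``C`` and a distal (systemic-vascular) resistance ``Rd``.  During
systolic ejection the target ventricular pressure is

    P = L*dQ/dt + Q*Rp + Pc

where ``Pc`` is the pressure on the compliance, i.e. the running integral
(1/C) * int(Q - Q_Rd) dt + P_C0 carried as a continuous state across beats,
with ``Q_Rd = Pc/Rd`` the runoff through the distal resistance.  Outside
ejection the (virtual) aortic valve is closed, Q = 0, and ``Pc`` relaxes
along the RC discharge

    Pc(t) = Pces * exp(-t / (Rd*C))

which doubles as the analytic oracle for the numerical compliance update.

Impedance components are in cgs units (Barye-based, see :mod:`pvloop.units`);
``Pc`` and all returned pressures are in mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .units import MMHG_TO_BARYE

#: Hard upper bound on the control step, s.  The supervisory software
#: recomputes the target pressure at intervals dt < 4 ms.
MAX_CONTROL_STEP_S = 0.004


@dataclass(frozen=True)
class ImpedanceParams:
    """Components of the virtual impedance (cgs units).

    Defaults are the device's standard settings.

    Attributes
    ----------
    L : float
        Inertance, Barye*s^2/cm^3.  Counteracts flow change.
    inv_C : float
        Inverse compliance 1/C, Barye/cm^3.  Aortic stretching capacity.
    Rp : float
        Proximal flow resistance (aortic valve), Barye*s/cm^3.
    Rd : float
        Distal flow resistance (distal track / SVR), Barye*s/cm^3.
    """

    L: float = 0.7
    inv_C: float = 420.0
    Rp: float = 24.5
    Rd: float = 404.6

    def __post_init__(self) -> None:
        for name in ("L", "inv_C", "Rp", "Rd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"impedance parameter {name} must be finite and > 0, got {v}")

    @property
    def C(self) -> float:
        """Compliance, cm^3/Barye."""
        return 1.0 / self.inv_C

    @property
    def tau_s(self) -> float:
        """RC discharge time constant Rd*C, s."""
        return self.Rd / self.inv_C


@dataclass(frozen=True)
class AfterloadState:
    """State of the virtual arterial load.

    Attributes
    ----------
    Pc : float
        Virtual aortic (compliance) pressure, mmHg.
    t_since_closure : float
        Seconds since aortic-valve closure; 0 during ejection.
    Pces : float
        Compliance pressure at end of ejection (valve closure), mmHg.
    P_C0 : float
        Compliance pressure at the start of the current/last systolic
        ejection phase, mmHg.
    """

    Pc: float = 60.0
    t_since_closure: float = 0.0
    Pces: float = 60.0
    P_C0: float = 60.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Pc) and self.Pc >= 0):
            raise ValueError(f"Pc must be finite and >= 0, got {self.Pc}")
        if self.t_since_closure < 0:
            raise ValueError("t_since_closure must be >= 0")


@dataclass(frozen=True)
class FlowSample:
    """Instantaneous ventricular outflow and derived quantities.

    ``Q`` is the flow out of the ventricle in cm^3/s (>= 0 during ejection,
    0 in the other phases), ``dQdt`` its time derivative in cm^3/s^2, and
    ``Q_Rd`` the runoff through the distal resistance in cm^3/s.
    """

    Q: float
    dQdt: float = 0.0
    Q_Rd: float = 0.0


def distal_runoff(params: ImpedanceParams, state: AfterloadState) -> float:
    """Flow through the distal resistance, Q_Rd = Pc/Rd, in cm^3/s."""
    return state.Pc * MMHG_TO_BARYE / params.Rd


def target_pressure(params: ImpedanceParams, flow: FlowSample, state: AfterloadState) -> float:
    """Target ventricular pressure during systolic ejection, in mmHg.

    P = L*dQ/dt + Q*Rp + Pc, with the L and Rp terms evaluated in Barye and
    converted to mmHg before summation with the compliance pressure state
    (the realized value of (1/C)*int(Q - Q_Rd)dt + P_C0).
    """
    if not (math.isfinite(flow.Q) and math.isfinite(flow.dQdt)):
        raise ValueError("flow sample must be finite")
    if flow.Q < 0:
        raise ValueError(f"outflow must be >= 0 during ejection, got Q={flow.Q}")
    cgs_terms = params.L * flow.dQdt + flow.Q * params.Rp
    return cgs_terms / MMHG_TO_BARYE + state.Pc


def step_compliance(
    params: ImpedanceParams, state: AfterloadState, Q: float, dt: float
) -> AfterloadState:
    """Advance the compliance pressure by one control step.

    Integrates dPc/dt = (Q - Q_Rd)/C with Q_Rd = Pc/Rd using one classical
    4th-order Runge-Kutta step, holding the ventricular outflow ``Q``
    (cm^3/s) constant over the step.  ``dt`` must respect the < 4 ms control
    contract.  ``t_since_closure`` accumulates while the valve is closed
    (Q == 0) and resets during ejection.
    """
    if not (0 < dt <= MAX_CONTROL_STEP_S):
        raise ValueError(f"control step dt={dt} s violates 0 < dt <= {MAX_CONTROL_STEP_S} s")
    if not math.isfinite(Q):
        raise ValueError("Q must be finite")

    # dPc/dt = alpha - beta*Pc  (Pc in mmHg; Q charging, Pc/Rd draining)
    alpha = Q * params.inv_C / MMHG_TO_BARYE
    beta = params.inv_C / params.Rd

    def f(p: float) -> float:
        return alpha - beta * p

    p = state.Pc
    k1 = f(p)
    k2 = f(p + 0.5 * dt * k1)
    k3 = f(p + 0.5 * dt * k2)
    k4 = f(p + dt * k3)
    p_new = p + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    p_new = max(p_new, 0.0)

    t_closed = 0.0 if Q > 0 else state.t_since_closure + dt
    return replace(state, Pc=p_new, t_since_closure=t_closed)


def decay_pressure(params: ImpedanceParams, Pces: float, t: float) -> float:
    """Closed-form RC discharge of the virtual aortic pressure, in mmHg.

    Pc(t) = Pces * exp(-t/(Rd*C)) for t seconds since aortic-valve closure.
    This is the analytic oracle for :func:`step_compliance` with Q = 0.
    """
    if t < 0:
        raise ValueError(f"time since valve closure must be >= 0, got {t}")
    if not (math.isfinite(Pces) and Pces >= 0):
        raise ValueError(f"Pces must be finite and >= 0, got {Pces}")
    return Pces * math.exp(-t / params.tau_s)
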