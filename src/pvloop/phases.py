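"""Four-phase cardiac-cycle detection.

Each control step is labeled as one of the four phases of the cardiac cycle
— diastolic filling (1), isovolumetric contraction (2), systolic ejection
(3), isovolumetric relaxation (4) — from the measured ventricular pressure
and the volume displacement observed over the step:

* FILLING -> ISO_CONTRACTION when a small outward volume displacement from
  the ventricular cavity is detected (dV > eps_out);
* ISO_CONTRACTION -> EJECTION when the ventricular pressure reaches the
  threshold pressure (the current virtual aortic pressure Pc);
* EJECTION -> ISO_RELAXATION when a small inward volume displacement to the
  cavity is detected (dV < -eps_in);
* ISO_RELAXATION -> FILLING when the ventricular pressure falls below the
  preload setpoint.

Transitions are checked in cycle order and at most one fires per control
step, so the emitted label sequence can only ever walk the cycle
1 -> 2 -> 3 -> 4 -> 1.  The displacement thresholds give the detector its
hysteresis: zero-mean volume noise smaller than eps never triggers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum


class Phase(IntEnum):
    """Cardiac-cycle phases, numbered as in the device's convention."""

    FILLING = 1
    ISO_CONTRACTION = 2
    EJECTION = 3
    ISO_RELAXATION = 4


#: Cycle successor of each phase.
_NEXT = {
    Phase.FILLING: Phase.ISO_CONTRACTION,
    Phase.ISO_CONTRACTION: Phase.EJECTION,
    Phase.EJECTION: Phase.ISO_RELAXATION,
    Phase.ISO_RELAXATION: Phase.FILLING,
}


@dataclass(frozen=True)
class PhaseState:
    """Current phase plus the volume-displacement detection thresholds.

    ``eps_out``/``eps_in`` (cm^3) are the outward/inward displacement
    magnitudes that mark the start and end of ejection-directed motion;
    they default to 0.1 cm^3, roughly 0.3% of an ovine stroke volume —
    small against any real displacement, large against sensor noise.
    """

    phase: Phase = Phase.FILLING
    eps_out: float = 0.1
    eps_in: float = 0.1

    def __post_init__(self) -> None:
        if not (self.eps_out > 0 and self.eps_in > 0):
            raise ValueError("displacement thresholds eps_out and eps_in must be > 0")


def advance(
    state: PhaseState,
    P_lv: float,
    dV: float,
    P_threshold: float,
    P_preload: float,
) -> PhaseState:
    """Advance the phase detector by one control step.

    Parameters
    ----------
    state : PhaseState
        Detector state entering the step.
    P_lv : float
        Measured left-ventricular pressure, mmHg.
    dV : float
        Signed volume displacement over this control step, cm^3;
        positive = volume leaving the ventricular cavity.
    P_threshold : float
        Ejection threshold pressure, mmHg — the current virtual aortic
        pressure Pc.
    P_preload : float
        Active preload setpoint, mmHg.

    Returns
    -------
    PhaseState
        The state after at most one cycle-ordered transition.
    """
    if not (math.isfinite(P_lv) and math.isfinite(dV)):
        raise ValueError("P_lv and dV must be finite")

    p = state.phase
    if p is Phase.FILLING and dV > state.eps_out:
        p = Phase.ISO_CONTRACTION
    elif p is Phase.ISO_CONTRACTION and P_lv >= P_threshold:
        p = Phase.EJECTION
    elif p is Phase.EJECTION and dV < -state.eps_in:
        p = Phase.ISO_RELAXATION
    elif p is Phase.ISO_RELAXATION and P_lv < P_preload:
        p = Phase.FILLING

    return state if p is state.phase else replace(state, phase=p)
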