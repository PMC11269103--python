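"""Closed-loop supervisor: preload control, virtual afterload, protocol.

At each control step (dt <= 4 ms) the supervisor selects the piston action
for the current cardiac phase:

* FILLING — proportional pressure regulation toward the preload setpoint.
  The piston is bidirectional: it injects fluid while ventricular pressure
  is below the setpoint and yields (is pushed back) once the contracting
  ventricle drives pressure above it; that outward displacement is exactly
  what the phase detector uses to mark the start of isovolumetric
  contraction.
* ISO_CONTRACTION / ISO_RELAXATION — piston held, Q = 0, volume constant.
* EJECTION — the ventricle ejects against the virtual impedance; the
  outflow evolves through the inertance, dQ/dt = (P_lv - Q*Rp - Pc)/L,
  which closes the algebraic loop between the measured ventricular
  pressure and the afterload equation.

The balloon and cylinder form a fluid-tight system: every cm^3 leaving the
balloon enters the cylinder, so balloon + cylinder volume is constant by
construction.  The preload setpoint may be changed at any time but takes
effect only at the next entry into the filling phase (i.e. after the
current cardiac cycle), and the stepped preload-challenge protocol raises
it level by level.

Convention: flows are positive *out of* the ventricle (ejection direction);
a negative piston flow during filling is inflow to the balloon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import impedance as imp_mod
from .heart import HeartParams, ed_volume, lv_pressure
from .impedance import MAX_CONTROL_STEP_S, AfterloadState, ImpedanceParams, step_compliance
from .phases import Phase, PhaseState, advance
from .trace import WaveformTrace, trace_from_arrays
from .units import MMHG_TO_BARYE

log = logging.getLogger(__name__)


class SimulationDivergedError(RuntimeError):
    """Raised when the closed-loop state becomes non-finite."""

    def __init__(self, level: float, beat: int, detail: str) -> None:
        super().__init__(
            f"simulation diverged at preload level {level} mmHg, beat {beat}: {detail}"
        )
        self.level = level
        self.beat = beat


@dataclass(frozen=True)
class ControllerConfig:
    """Supervisor configuration.

    Attributes
    ----------
    dt : float
        Control step, s; must respect the < 4 ms contract.
    preload_setpoint : float
        Target filling pressure, mmHg.
    motor_gain : float
        Proportional gain of the filling regulator, cm^3/(s*mmHg).
    total_volume : float
        Constant, preset balloon + cylinder fluid volume, cm^3.
    p_aorta_init : float
        Initial virtual aortic pressure, mmHg (state, decays/recharges
        freely after the first beats).
    eps_out, eps_in : float
        Phase-detector displacement thresholds, cm^3.
    """

    dt: float = 0.001
    preload_setpoint: float = 10.0
    motor_gain: float = 50.0
    total_volume: float = 250.0
    p_aorta_init: float = 60.0
    eps_out: float = 0.1
    eps_in: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.dt <= MAX_CONTROL_STEP_S):
            raise ValueError(
                f"control step dt={self.dt} s violates the contract 0 < dt <= "
                f"{MAX_CONTROL_STEP_S} s"
            )
        if not self.preload_setpoint > 0:
            raise ValueError("preload_setpoint must be > 0")
        if not self.total_volume > 0:
            raise ValueError("total_volume must be > 0")
        if not self.motor_gain > 0:
            raise ValueError("motor_gain must be > 0")


@dataclass(frozen=True)
class RampProtocol:
    """Stepped preload challenge: start, start+step, ..., stop (mmHg).

    Defaults follow the assessment protocol: preload from 10 to 25 mmHg in
    5 mmHg increments, each level recorded for ``dwell`` seconds.
    """

    start: float = 10.0
    stop: float = 25.0
    step: float = 5.0
    dwell: float = 60.0

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError("protocol start must be <= stop")
        if not self.step > 0:
            raise ValueError("protocol step must be > 0")
        if not self.dwell > 0:
            raise ValueError("protocol dwell must be > 0")

    def levels(self) -> list[float]:
        """Preload levels in mmHg, inclusive of both ends."""
        out = []
        k = 0
        while True:
            lv = self.start + k * self.step
            if lv > self.stop + 1e-9:
                break
            out.append(float(lv))
            k += 1
        return out


def set_preload(cfg: ControllerConfig, new: float) -> ControllerConfig:
    """Return a config with a new preload setpoint (mmHg).

    The running simulator applies a changed setpoint at the next entry into
    the filling phase, never mid-beat.
    """
    if not (math.isfinite(new) and new > 0):
        raise ValueError(f"preload setpoint must be finite and > 0, got {new}")
    return replace(cfg, preload_setpoint=new)


def control_step(
    cfg: ControllerConfig,
    phase: Phase,
    P_lv: float,
    params: ImpedanceParams,
    state: AfterloadState,
    Q_prev: float = 0.0,
) -> float:
    """One supervisor step: the piston flow command Q in cm^3/s.

    Positive Q moves volume out of the ventricle.  FILLING returns the
    proportional command ``motor_gain * (P_lv - preload_setpoint)``; the
    isovolumetric phases hold Q = 0 exactly; EJECTION advances the outflow
    through the inertance by one step of dQ/dt = (P_lv - Q*Rp - Pc)/L with
    the pressures held over the step (the linear ODE is advanced by its
    exact exponential update).
    """
    if not math.isfinite(P_lv):
        raise SimulationDivergedError(cfg.preload_setpoint, -1, f"non-finite P_lv={P_lv}")
    if phase is Phase.FILLING:
        return cfg.motor_gain * (P_lv - cfg.preload_setpoint)
    if phase in (Phase.ISO_CONTRACTION, Phase.ISO_RELAXATION):
        return 0.0
    # EJECTION: relax Q toward (P_lv - Pc)/Rp with time constant L/Rp.
    q_inf = (P_lv - state.Pc) * MMHG_TO_BARYE / params.Rp
    decay = math.exp(-params.Rp * cfg.dt / params.L)
    return q_inf + (Q_prev - q_inf) * decay


@dataclass
class LoopSimulator:
    """Closed-loop simulation of the synthetic heart on the PV-loop system.

    Holds the full device + ventricle state and advances it one control
    step at a time; :func:`run_protocol` drives it through a preload ramp.
    """

    cfg: ControllerConfig
    heart: HeartParams
    params: ImpedanceParams = field(default_factory=ImpedanceParams)

    def __post_init__(self) -> None:
        self.t = 0.0
        self.V = self._initial_volume()
        self.V_cyl = self.cfg.total_volume - self.V
        if self.V_cyl <= 0:
            raise ValueError(
                "total_volume too small: cylinder volume would be non-positive "
                f"({self.V_cyl} cm^3)"
            )
        self.Q = 0.0
        self.dV_prev = 0.0
        self.phase_state = PhaseState(
            Phase.FILLING, eps_out=self.cfg.eps_out, eps_in=self.cfg.eps_in
        )
        self.after = AfterloadState(
            Pc=self.cfg.p_aorta_init,
            Pces=self.cfg.p_aorta_init,
            P_C0=self.cfg.p_aorta_init,
        )
        self.active_setpoint = self.cfg.preload_setpoint
        self.pending_setpoint = self.cfg.preload_setpoint
        self.beat = 0
        self.max_volume_error = 0.0
        self.rng = np.random.default_rng(self.heart.seed)

    def _initial_volume(self) -> float:
        """Passive equilibrium volume at the initial preload setpoint."""
        try:
            return ed_volume(self.heart, self.cfg.preload_setpoint)
        except ValueError:
            return self.heart.V0 + 30.0

    def request_preload(self, new: float) -> None:
        """Request a setpoint change; applied at the next FILLING entry."""
        if not (math.isfinite(new) and new > 0):
            raise ValueError(f"preload setpoint must be finite and > 0, got {new}")
        self.pending_setpoint = new

    def step(self, level_label: float) -> tuple[float, float, float, float, int]:
        """Advance one control step; return the sample recorded at entry time.

        The sample is (time, measured pressure, balloon volume, piston flow
        applied over the step, phase code); volume obeys
        ``V[i+1] = V[i] - q[i]*dt`` exactly.
        """
        cfg, heart, params = self.cfg, self.heart, self.params
        dt = cfg.dt

        p_meas = lv_pressure(heart, self.V, self.t, self.rng)
        if not math.isfinite(p_meas) or not math.isfinite(self.V):
            raise SimulationDivergedError(level_label, self.beat, "non-finite state")

        prev = self.phase_state.phase
        self.phase_state = advance(
            self.phase_state, p_meas, self.dV_prev, self.after.Pc, self.active_setpoint
        )
        phase = self.phase_state.phase
        if phase is not prev:
            self.Q = 0.0
            if log.isEnabledFor(logging.DEBUG):
                log.debug(
                    "t=%.4f s beat=%d: %s -> %s (P_lv=%.2f mmHg, Pc=%.2f mmHg)",
                    self.t, self.beat, prev.name, phase.name, p_meas, self.after.Pc,
                )
            if phase is Phase.EJECTION:
                self.after = replace(self.after, P_C0=self.after.Pc, t_since_closure=0.0)
            elif phase is Phase.ISO_RELAXATION:
                self.after = replace(self.after, Pces=self.after.Pc, t_since_closure=0.0)
            elif phase is Phase.FILLING:
                if self.pending_setpoint != self.active_setpoint:
                    log.debug(
                        "t=%.4f s beat=%d: preload setpoint %.1f -> %.1f mmHg",
                        self.t, self.beat, self.active_setpoint, self.pending_setpoint,
                    )
                self.active_setpoint = self.pending_setpoint
                self.beat += 1

        if phase is Phase.EJECTION:
            q_new = control_step(cfg, phase, p_meas, params, self.after, self.Q)
            q_applied = 0.5 * (self.Q + q_new)
            self.after = step_compliance(params, self.after, q_applied, dt)
            self.Q = q_new
        elif phase is Phase.FILLING:
            q_applied = control_step(cfg_with_setpoint(cfg, self.active_setpoint),
                                     phase, p_meas, params, self.after, self.Q)
            self.after = step_compliance(params, self.after, 0.0, dt)
            self.Q = q_applied
        else:
            q_applied = 0.0
            self.after = step_compliance(params, self.after, 0.0, dt)
            self.Q = 0.0

        sample = (self.t, p_meas, self.V, q_applied, int(phase))

        dV = q_applied * dt  # outward displacement this step
        self.V -= dV
        self.V_cyl += dV
        if self.V < 0:
            raise SimulationDivergedError(level_label, self.beat, "balloon volume < 0")
        err = abs(self.V + self.V_cyl - cfg.total_volume)
        if err > self.max_volume_error:
            self.max_volume_error = err
        self.dV_prev = dV
        self.t += dt
        return sample

    def run(self, duration: float, level_label: float) -> WaveformTrace:
        """Simulate ``duration`` seconds and return the labeled trace."""
        n = int(round(duration / self.cfg.dt))
        ts = np.empty(n)
        ps = np.empty(n)
        vs = np.empty(n)
        qs = np.empty(n)
        ph = np.empty(n, dtype=np.int64)
        for i in range(n):
            ts[i], ps[i], vs[i], qs[i], ph[i] = self.step(level_label)
        lev = np.full(n, level_label)
        return trace_from_arrays(ts, ps, vs, qs, ph, lev)


def cfg_with_setpoint(cfg: ControllerConfig, setpoint: float) -> ControllerConfig:
    """Config view with the currently *active* (beat-synchronous) setpoint."""
    if setpoint == cfg.preload_setpoint:
        return cfg
    return replace(cfg, preload_setpoint=setpoint)


def run_protocol(
    cfg: ControllerConfig,
    protocol: RampProtocol,
    heart: HeartParams,
    params: ImpedanceParams | None = None,
    warmup_s: float = 8.0,
) -> list[WaveformTrace]:
    """Execute the stepped preload challenge; one trace per preload level.

    Each level ``start, start+step, ..., stop`` is held for
    ``protocol.dwell`` seconds; setpoint changes are applied at the next
    filling-phase entry.  The final active setpoint equals ``protocol.stop``.

    Before recording, the loop beats for ``warmup_s`` seconds at the first
    level (discarded) so the virtual aorta reaches its periodic steady
    state — the analogue of the heart beating on the device before the
    recording is started.
    """
    params = params if params is not None else ImpedanceParams()
    levels = protocol.levels()
    sim = LoopSimulator(set_preload(cfg, levels[0]), heart, params)
    if warmup_s > 0:
        sim.run(warmup_s, levels[0])
    out: list[WaveformTrace] = []
    for lv in levels:
        sim.request_preload(lv)
        out.append(sim.run(protocol.dwell, lv))
    return out
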