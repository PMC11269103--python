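"""Pressure-volume loop metrics: dP/dt, stroke work, ESPVR, EDPVR, Tau.

Beats are segmented at ISO_RELAXATION -> FILLING transitions of the
phase-labeled trace.  Per beat the suite reports dP/dt extrema (central
differences), maximal pressure, the end-diastolic and end-systolic
pressure-volume points, stroke work (shoelace loop area) and the
isovolumic-relaxation time constant Tau.

Across a preload ramp, the end-systolic elastance Ees is the slope of the
end-systolic pressure-volume relationship (ESPVR), P = Ees*(V - V0), fitted
by ordinary least squares over per-level end-systolic points.  Because the
phase detector marks the ejection/relaxation boundary only after its
inward-displacement hysteresis is exceeded — by which time activation has
already declined — the default end-systolic point is found by a maximal
elastance search: per beat, the ejection sample maximizing P/(V - V0_fit),
with V0_fit taken from the ESPVR fit itself and iterated to convergence
(initialized from the last forward-flow sample, i.e. aortic-valve closure).
The raw phase-transition sample is available as ``es_method="phase"`` for
sensitivity checks.

Tau follows the Weiss convention: a mono-exponential P(t) = P_a*exp(-t/tau)
fitted on the window from the time of dP/dt_min to the end of isovolumic
relaxation; the Glantz variant adds a non-zero asymptote P_b.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trace import WaveformTrace
from .phases import Phase

ES_METHODS = ("max-elastance", "reversal", "phase")
TAU_METHODS = ("weiss", "glantz")


@dataclass
class LoopMetrics:
    """Per-beat functional metrics.

    Pressures in mmHg, volumes in cm^3, dP/dt in mmHg/s, tau in ms,
    stroke work in mmHg*cm^3.  ``flags`` lists quality problems; a metric
    that could not be computed is NaN with a corresponding flag.
    """

    dpdt_max: float = math.nan
    dpdt_min: float = math.nan
    p_max: float = math.nan
    edv: float = math.nan
    esv: float = math.nan
    sv: float = math.nan
    stroke_work: float = math.nan
    tau: float = math.nan
    ed_point: tuple[float, float] = (math.nan, math.nan)
    es_point: tuple[float, float] = (math.nan, math.nan)
    preload_level: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.flags


@dataclass
class EDPVRFit:
    """End-diastolic pressure-volume relationship fit.

    ``form`` is "exponential" (P = A*(exp(B*(V - V_ref)) - 1)) or "linear"
    (P = slope*V + intercept), whichever is preferred by AIC (or linear as
    fallback when the exponential fit fails to converge).
    """

    form: str
    A: float = math.nan
    B: float = math.nan
    V_ref: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    aic_exponential: float = math.nan
    aic_linear: float = math.nan

    def predict(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if self.form == "exponential":
            return self.A * np.expm1(self.B * (V - self.V_ref))
        return self.slope * V + self.intercept


@dataclass
class RampResult:
    """Result of a preload-ramp PV-loop analysis."""

    Ees: float
    V0_fit: float
    espvr_r2: float
    edpvr: EDPVRFit | None
    levels: list[float]
    beats: list[LoopMetrics]
    es_method: str
    tau_method: str
    n_beats_used: int
    settle_beats: int


def segment_beats(trace: WaveformTrace) -> list[WaveformTrace]:
    """Split a phase-labeled trace into complete beats.

    Beats are delimited at ISO_RELAXATION -> FILLING transitions, so each
    returned beat starts in FILLING; incomplete leading and trailing beats
    are discarded.  Returns an empty list (with a warning) when the trace
    holds no complete beat.
    """
    ph = trace.phase
    if len(ph) < 2:
        warnings.warn("trace holds no complete beat", stacklevel=2)
        return []
    starts = np.where((ph[:-1] == int(Phase.ISO_RELAXATION)) & (ph[1:] == int(Phase.FILLING)))[0] + 1
    beats = [
        WaveformTrace(trace.data.iloc[a:b]) for a, b in zip(starts[:-1], starts[1:])
    ]
    if not beats:
        warnings.warn("trace holds no complete beat", stacklevel=2)
    return beats


def _phase_slices(beat: WaveformTrace) -> dict[int, np.ndarray]:
    ph = beat.phase
    return {p: np.where(ph == p)[0] for p in (1, 2, 3, 4)}


def _es_index(beat: WaveformTrace, es_method: str, v0: float | None) -> int | None:
    """Index of the end-systolic sample within the beat, or None."""
    idx = _phase_slices(beat)
    ej = idx[int(Phase.EJECTION)]
    if len(ej) == 0:
        return None
    if es_method == "phase":
        return int(ej[-1])
    if es_method == "max-elastance" and v0 is not None:
        v = beat.volume[ej]
        p = beat.pressure[ej]
        with np.errstate(divide="ignore", invalid="ignore"):
            el = np.where(v - v0 > 1e-9, p / (v - v0), -np.inf)
        return int(ej[int(np.argmax(el))])
    # "reversal" (and max-elastance before a V0 estimate exists):
    # last sample of forward outflow = aortic-valve closure.
    fwd = ej[beat.flow[ej] >= 0]
    return int(fwd[-1]) if len(fwd) else int(ej[-1])


def shoelace_area(v: np.ndarray, p: np.ndarray) -> float:
    """Unsigned area of the closed (V, P) polygon, mmHg*cm^3."""
    return 0.5 * abs(float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1))))


def beat_metrics(
    beat: WaveformTrace,
    es_method: str = "max-elastance",
    v0: float | None = None,
    tau_method: str = "weiss",
) -> LoopMetrics:
    """Functional metrics for one segmented beat.

    ``v0`` is the ESPVR volume intercept used by the maximal-elastance
    end-systolic search; without it the valve-closure (flow-reversal)
    sample is used.  A beat missing any of the four phases is returned
    flagged invalid.
    """
    if es_method not in ES_METHODS:
        raise ValueError(f"unknown es_method {es_method!r}; choose from {ES_METHODS}")
    m = LoopMetrics()
    if len(beat) >= 1:
        m.preload_level = float(beat.preload_level[0])
    idx = _phase_slices(beat)
    missing = [p for p, ix in idx.items() if len(ix) == 0]
    if missing:
        m.flags.append(f"missing phase(s) {missing}")
        return m

    t, p, v = beat.time, beat.pressure, beat.volume
    dpdt = np.gradient(p, t)
    m.dpdt_max = float(dpdt.max())
    m.dpdt_min = float(dpdt.min())
    m.p_max = float(p.max())
    m.stroke_work = shoelace_area(v, p)

    i_ed = int(idx[int(Phase.FILLING)][-1])  # FILLING -> ISO_CONTRACTION transition
    m.ed_point = (float(v[i_ed]), float(p[i_ed]))
    m.edv = float(v[i_ed])

    i_es = _es_index(beat, es_method, v0)
    m.es_point = (float(v[i_es]), float(p[i_es]))
    m.esv = float(v[i_es])
    m.sv = m.edv - m.esv

    try:
        m.tau = fit_tau(beat, method=tau_method)
    except ValueError as exc:
        m.flags.append(f"tau: {exc}")
    return m


def fit_espvr(
    es_points: "np.ndarray | list[tuple[float, float]]",
    levels: "np.ndarray | list[float] | None" = None,
) -> tuple[float, float, float]:
    """Fit the ESPVR line P = Ees*(V - V0) by ordinary least squares.

    ``es_points`` are (V, P) pairs, one or more per preload level; when
    ``levels`` is given, points are averaged per level before fitting and
    at least two distinct levels are required.  Returns
    ``(Ees, V0_fit, r2)`` with Ees in mmHg/mL.
    """
    pts = np.asarray(es_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("es_points must be an (n, 2) array of (V, P) pairs")
    if levels is not None:
        levels = np.asarray(levels, dtype=float)
        if levels.shape[0] != pts.shape[0]:
            raise ValueError("levels must align with es_points")
        uniq = np.unique(levels)
        if uniq.size < 2:
            raise ValueError("ESPVR fit requires points from >= 2 distinct preload levels")
        pts = np.array([pts[levels == lv].mean(axis=0) for lv in uniq])
    if pts.shape[0] < 2:
        raise ValueError("ESPVR fit requires >= 2 end-systolic points")
    V, P = pts[:, 0], pts[:, 1]
    if np.ptp(V) < 1e-12 or np.allclose(V, V[0]):
        raise ValueError("zero volume variance: ESPVR slope undefined")
    res = stats.linregress(V, P)
    ees = float(res.slope)
    if ees == 0:
        raise ValueError("degenerate ESPVR fit: zero slope")
    v0 = float(-res.intercept / ees)
    return ees, v0, float(res.rvalue**2)


def fit_edpvr(ed_points: "np.ndarray | list[tuple[float, float]]") -> EDPVRFit:
    """Fit the passive (end-diastolic) pressure-volume relationship.

    Tries the exponential form P = A*(exp(B*(V - V_ref)) - 1) by nonlinear
    least squares (V_ref = smallest end-diastolic volume) and a straight
    line; the form preferred by AIC is reported.  Falls back to the linear
    form, with a warning, when the exponential fit does not converge.
    """
    pts = np.asarray(ed_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("ed_points must be an (n, 2) array of (V, P) pairs")
    if pts.shape[0] < 2:
        raise ValueError("EDPVR fit requires >= 2 points")
    V, P = pts[:, 0], pts[:, 1]
    if np.ptp(V) < 1e-12:
        raise ValueError("zero volume variance: EDPVR fit undefined")

    n = V.size
    lin = stats.linregress(V, P)
    rss_lin = float(np.sum((P - (lin.slope * V + lin.intercept)) ** 2))
    aic_lin = _aic(n, rss_lin, k=2)

    fit = EDPVRFit(
        form="linear", slope=float(lin.slope), intercept=float(lin.intercept),
        V_ref=float(V.min()), aic_linear=aic_lin,
    )
    try:
        span = max(np.ptp(V), 1.0)
        b0 = math.log(max(P.max(), 1e-3) / max(P.min(), 1e-3) + 1.0) / span
        a0 = max(P.min(), 0.5)

        def expn(v, a, b, vr):
            return a * np.expm1(b * (v - vr))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # V_ref is a free shift (the volume where passive pressure is 0);
            # with it fixed the form cannot absorb any pressure offset.
            (A, B, v_ref), _ = optimize.curve_fit(
                expn, V, P, p0=(a0, max(b0, 1e-3), float(V.min()) - 1.0),
                bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, float(V.min())]),
                maxfev=20000,
            )
        rss_exp = float(np.sum((P - expn(V, A, B, v_ref)) ** 2))
        aic_exp = _aic(n, rss_exp, k=3)
        fit.A, fit.B, fit.V_ref = float(A), float(B), float(v_ref)
        fit.aic_exponential = aic_exp
        if aic_exp < aic_lin:
            fit.form = "exponential"
    except (RuntimeError, TypeError):
        warnings.warn("EDPVR exponential fit did not converge; using linear form",
                      stacklevel=2)
    return fit


def _aic(n: int, rss: float, k: int) -> float:
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


def fit_exponential_decay(
    t: np.ndarray, p: np.ndarray, method: str = "weiss"
) -> float:
    """Time constant (ms) of an exponential pressure decay segment.

    Weiss: log-linear fit of P(t) = P_a*exp(-t/tau), requiring P > 0.
    Glantz: nonlinear fit of P(t) = (P_0 - P_b)*exp(-t/tau) + P_b with a
    free asymptote P_b.
    """
    if method not in TAU_METHODS:
        raise ValueError(f"unknown tau method {method!r}; choose from {TAU_METHODS}")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 5:
        raise ValueError("relaxation window needs >= 5 samples")
    if np.ptp(p) < 1e-12:
        raise ValueError("constant-pressure segment: decay undefined")
    t = t - t[0]
    if method == "weiss":
        if np.any(p <= 0):
            pos = p > 0
            if pos.sum() < 5:
                raise ValueError("too few positive-pressure samples for log-linear fit")
            t, p = t[pos], p[pos]
        res = stats.linregress(t, np.log(p))
        if res.slope >= 0:
            raise ValueError("pressure does not decay over the relaxation window")
        return float(-1000.0 / res.slope)
    # Glantz
    p0 = p[0]
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
    (pa, pb, tau), _ = optimize.curve_fit(
        lambda tt, pa_, pb_, tau_: (pa_ - pb_) * np.exp(-tt / tau_) + pb_,
        t, p, p0=(p0, min(p.min(), 0.0), tau0), maxfev=20000,
    )
    if tau <= 0:
        raise ValueError("non-physical (non-positive) relaxation time constant")
    return float(tau * 1000.0)


def fit_tau(beat: WaveformTrace, method: str = "weiss") -> float:
    """Isovolumic-relaxation time constant Tau for one beat, in ms.

    The fitting window runs from the time of dP/dt_min to the end of the
    ISO_RELAXATION segment (Weiss convention).  Raises ``ValueError`` when
    the window is too short, non-decaying, or the fit fails.
    """
    idx = np.where(beat.phase == int(Phase.ISO_RELAXATION))[0]
    if idx.size < 5:
        raise ValueError("isovolumic relaxation segment needs >= 5 samples")
    t, p = beat.time, beat.pressure
    dpdt = np.gradient(p, t)
    i_min = int(np.argmin(dpdt))
    lo = max(i_min, int(idx[0]))
    hi = int(idx[-1]) + 1
    if hi - lo < 5:
        lo = int(idx[0])
    window = slice(lo, hi)
    pw = p[window]
    if np.any(np.diff(pw) > 0):
        # allow tiny non-monotonicity from sensor noise, flag real reversals
        rises = np.diff(pw)
        if rises.max() > 0.05 * max(np.ptp(pw), 1e-9):
            raise ValueError("non-monotone relaxation window")
    return fit_exponential_decay(t[window], pw, method=method)


def analyze_ramp(
    traces: "WaveformTrace | list[WaveformTrace]",
    es_method: str = "max-elastance",
    tau_method: str = "weiss",
    settle_beats: int = 2,
    max_iter: int = 10,
) -> RampResult:
    """Full PV-loop analysis of a preload-ramp recording.

    Segments beats, discards ``settle_beats`` settling beats at the start
    of each preload level, computes per-beat metrics, and fits the ESPVR
    (with the iterative maximal-elastance end-systolic search unless
    ``es_method`` says otherwise) and the EDPVR over per-level mean points.
    """
    if isinstance(traces, WaveformTrace):
        trace_list = traces.split_by_level()
    else:
        trace_list = list(traces)

    beats: list[WaveformTrace] = []
    for tr in trace_list:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bl = segment_beats(tr)
        beats.extend(bl[settle_beats:])
    complete = [b for b in beats if all(len(ix) for ix in _phase_slices(b).values())]
    if not complete:
        raise ValueError("no complete beats after settling discard")

    levels_arr = np.array([float(b.preload_level[0]) for b in complete])
    uniq_levels = [float(x) for x in np.unique(levels_arr)]
    if len(uniq_levels) < 2:
        raise ValueError("ESPVR fit requires >= 2 distinct preload levels")

    # Iterate the end-systolic search against the fitted volume intercept.
    v0: float | None = None
    ees = v0_fit = r2 = math.nan
    for _ in range(max_iter if es_method == "max-elastance" else 1):
        pts = []
        for b in complete:
            i = _es_index(b, es_method, v0)
            pts.append((b.volume[i], b.pressure[i]))
        ees, v0_fit, r2 = fit_espvr(pts, levels_arr)
        if es_method != "max-elastance":
            break
        if v0 is not None and abs(v0_fit - v0) < 1e-9:
            v0 = v0_fit
            break
        v0 = v0_fit

    metrics = [
        beat_metrics(b, es_method=es_method, v0=v0, tau_method=tau_method)
        for b in complete
    ]

    ed_pts = np.array([m.ed_point for m in metrics if m.valid or not math.isnan(m.edv)])
    ed_levels = np.array([m.preload_level for m in metrics if m.valid or not math.isnan(m.edv)])
    edpvr = None
    if len(ed_pts) >= 2:
        per_level = np.array(
            [ed_pts[ed_levels == lv].mean(axis=0) for lv in uniq_levels]
        )
        try:
            edpvr = fit_edpvr(per_level)
        except ValueError:
            edpvr = None

    return RampResult(
        Ees=ees,
        V0_fit=v0_fit,
        espvr_r2=r2,
        edpvr=edpvr,
        levels=uniq_levels,
        beats=metrics,
        es_method=es_method,
        tau_method=tau_method,
        n_beats_used=len(complete),
        settle_beats=settle_beats,
    )
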