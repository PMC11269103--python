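"""Analysis tests: beat segmentation, loop metrics, ESPVR/EDPVR/Tau fits."""

import math

import numpy as np
import pytest

from pvloop import (
    ControllerConfig,
    HeartParams,
    RampProtocol,
    WaveformTrace,
    analyze_ramp,
    beat_metrics,
    concat_traces,
    fit_edpvr,
    fit_espvr,
    fit_tau,
    run_protocol,
    segment_beats,
    trace_from_arrays,
)
from pvloop.analysis import fit_exponential_decay, shoelace_area


def labeled_trace(phases, pressures=None, volumes=None, dt=0.001, t0=0.0):
    n = len(phases)
    p = pressures if pressures is not None else np.full(n, 20.0)
    v = volumes if volumes is not None else np.full(n, 40.0)
    t = t0 + dt * np.arange(n)
    return trace_from_arrays(t, p, v, np.zeros(n), phases, np.full(n, 10.0))


def cycle_labels(n1=5, n2=3, n3=4, n4=3):
    return [1] * n1 + [2] * n2 + [3] * n3 + [4] * n4


class TestSegmentBeats:
    def test_complete_beats_extracted_partial_discarded(self):
        labels = [3, 4] + cycle_labels() * 5 + [1, 2]
        beats = segment_beats(labeled_trace(labels))
        assert len(beats) == 5
        assert all(b.phase[0] == 1 for b in beats)

    def test_empty_trace_gives_empty_list_with_warning(self):
        with pytest.warns(UserWarning, match="no complete beat"):
            assert segment_beats(WaveformTrace()) == []

    def test_single_complete_beat_starts_in_filling(self):
        labels = [4] + cycle_labels() + [4, 1, 1]
        beats = segment_beats(labeled_trace(labels))
        assert len(beats) == 1
        assert beats[0].phase[0] == 1


class TestBeatMetrics:
    def test_sinusoid_dpdt_extrema(self):
        """P(t) = 50 + 40*sin(2*pi*t) at constant volume: dP/dt extrema are
        +-80*pi mmHg/s up to central-difference truncation."""
        n = 1000
        dt = 0.001
        t = dt * np.arange(n)
        p = 50.0 + 40.0 * np.sin(2 * np.pi * t)
        labels = [1] * 250 + [2] * 250 + [3] * 250 + [4] * 250
        beat = labeled_trace(labels, pressures=p, dt=dt)
        m = beat_metrics(beat, es_method="phase")
        w = 2 * np.pi
        trunc = 40.0 * w * (w * dt) ** 2  # |f'''| h^2 / 6 bound, generous
        assert m.dpdt_max == pytest.approx(40.0 * w, abs=10 * trunc)
        assert m.dpdt_min == pytest.approx(-40.0 * w, abs=10 * trunc)
        assert m.p_max == pytest.approx(90.0, abs=1e-6)
        assert m.stroke_work == pytest.approx(0.0, abs=1e-9)

    def test_rectangle_loop_stroke_work(self):
        """A rectangular loop 20 cm^3 wide and 60 mmHg tall encloses
        1200 mmHg*cm^3."""
        v = np.concatenate([np.linspace(60, 40, 50), np.full(50, 40.0),
                            np.linspace(40, 60, 50), np.full(50, 60.0)])
        p = np.concatenate([np.full(50, 80.0), np.linspace(80, 20, 50),
                            np.full(50, 20.0), np.linspace(20, 80, 50)])
        assert shoelace_area(v, p) == pytest.approx(1200.0, rel=1e-2)

    def test_missing_phase_flags_beat_invalid(self):
        beat = labeled_trace([1] * 5 + [2] * 5 + [4] * 5)  # no ejection
        m = beat_metrics(beat)
        assert not m.valid
        assert any("missing phase" in f for f in m.flags)

    def test_end_systolic_point_on_elastance_line(self, ramp_trace_27, heart_27):
        """A noise-free simulated beat's ES point obeys P = 2.7*(V - V0)
        within 2%."""
        beats = segment_beats(ramp_trace_27.split_by_level()[0])[2:]
        m = beat_metrics(beats[0], es_method="max-elastance", v0=heart_27.V0)
        v_es, p_es = m.es_point
        assert p_es == pytest.approx(2.7 * (v_es - heart_27.V0), rel=0.02)
        assert m.edv >= m.esv
        assert m.dpdt_max > 0 > m.dpdt_min


class TestFitESPVR:
    def test_exact_collinear_points(self):
        ees, v0, r2 = fit_espvr([(10, 27), (20, 54), (30, 81)])
        assert ees == pytest.approx(2.7)
        assert v0 == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_symmetric_perturbation_leaves_slope_unchanged(self):
        """The middle point sits at the volume mean, so a +-eps pressure
        perturbation there cannot move the OLS slope."""
        base = np.array([(10.0, 27.0), (20.0, 54.0), (30.0, 81.0)])
        for eps in (0.5, -0.5):
            pts = base.copy()
            pts[1, 1] += eps
            ees, _, _ = fit_espvr(pts)
            assert ees == pytest.approx(2.7, rel=1e-12)

    def test_requires_two_distinct_levels(self):
        with pytest.raises(ValueError, match="levels"):
            fit_espvr([(10, 27), (11, 30)], levels=[10.0, 10.0])

    def test_rejects_zero_volume_variance(self):
        with pytest.raises(ValueError, match="volume variance"):
            fit_espvr([(20, 27), (20, 54)])

    def test_recovers_programmed_elastance_from_ramp(self, ramp_result_27):
        assert ramp_result_27.Ees == pytest.approx(2.7, rel=0.05)
        assert ramp_result_27.espvr_r2 > 0.99


class TestFitEDPVR:
    def test_round_trip_from_known_constants(self):
        A, B, v0 = 1.2, 0.06, 12.0
        V = np.linspace(45, 80, 6)
        P = A * np.expm1(B * (V - v0))
        fit = fit_edpvr(np.c_[V, P])
        assert fit.form == "exponential"
        assert fit.A == pytest.approx(A, rel=0.05)
        assert fit.B == pytest.approx(B, rel=0.05)

    def test_linear_points_select_linear_form(self):
        import warnings

        V = np.array([50.0, 60.0, 70.0, 80.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = fit_edpvr(np.c_[V, 0.5 * V - 10.0])
        assert fit.form == "linear"
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(-10.0)

    def test_rejects_single_repeated_volume(self):
        with pytest.raises(ValueError, match="volume variance"):
            fit_edpvr([(60.0, 10.0), (60.0, 12.0)])

    def test_rejects_single_point(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_edpvr([(60.0, 10.0)])


class TestFitTau:
    @pytest.mark.parametrize("tau_ms", [20.0, 40.0, 60.0])
    def test_pure_exponential_recovered(self, tau_ms):
        t = np.arange(0, 0.15, 0.001)
        p = 80.0 * np.exp(-t / (tau_ms / 1000.0))
        got = fit_exponential_decay(t, p, method="weiss")
        assert got == pytest.approx(tau_ms, rel=1e-3)

    def test_glantz_handles_asymptote_weiss_biased(self):
        """With a 5 mmHg asymptote the Weiss log-linear fit is biased long;
        the Glantz variant recovers the true constant."""
        t = np.arange(0, 0.15, 0.001)
        p = 75.0 * np.exp(-t / 0.040) + 5.0
        glantz = fit_exponential_decay(t, p, method="glantz")
        weiss = fit_exponential_decay(t, p, method="weiss")
        assert glantz == pytest.approx(40.0, rel=1e-3)
        assert weiss > 1.05 * 40.0

    def test_constant_segment_rejected(self):
        t = np.arange(0, 0.02, 0.001)
        with pytest.raises(ValueError, match="constant"):
            fit_exponential_decay(t, np.full(t.size, 30.0))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_exponential_decay(np.arange(3) * 1e-3, np.array([3.0, 2.0, 1.0]))

    def test_beat_window_starts_at_dpdt_min(self):
        """Tau fitted on a beat whose relaxation segment is an exact
        exponential recovers the programmed constant."""
        dt = 0.001
        n_pre = 30
        n_rel = 120
        p_pre = np.full(n_pre, 80.0)
        t_rel = dt * np.arange(n_rel)
        p_rel = 80.0 * np.exp(-t_rel / 0.040)
        labels = [1] * 10 + [2] * 10 + [3] * 10 + [4] * n_rel
        beat = labeled_trace(labels, pressures=np.concatenate([p_pre, p_rel]), dt=dt)
        assert fit_tau(beat) == pytest.approx(40.0, rel=5e-3)


class TestRampAnalysis:
    @pytest.mark.parametrize("ees_true", [1.0, 2.0, 2.7, 2.8, 4.0])
    def test_parameter_recovery_across_elastance_grid(self, ees_true, default_cfg,
                                                      ramp_protocol):
        """Noise-free recovery of the programmed elastance within 2% over
        the physiologic range."""
        heart = HeartParams(Ees_true=ees_true)
        traces = run_protocol(default_cfg, ramp_protocol, heart)
        res = analyze_ramp(concat_traces(traces))
        assert res.Ees == pytest.approx(ees_true, rel=0.02)
        assert res.V0_fit == pytest.approx(heart.V0, abs=1.0)

    def test_metrics_invariant_to_time_shift(self, ramp_trace_27):
        shifted = WaveformTrace(ramp_trace_27.data.assign(
            time_s=ramp_trace_27.time + 17.3))
        a = analyze_ramp(ramp_trace_27)
        b = analyze_ramp(shifted)
        assert b.Ees == pytest.approx(a.Ees, rel=1e-9)
        assert b.V0_fit == pytest.approx(a.V0_fit, rel=1e-9)
        ta = [m.tau for m in a.beats if not math.isnan(m.tau)]
        tb = [m.tau for m in b.beats if not math.isnan(m.tau)]
        assert tb == pytest.approx(ta, rel=1e-9)

    def test_phase_es_method_available_for_sensitivity(self, ramp_trace_27):
        res = analyze_ramp(ramp_trace_27, es_method="phase")
        assert math.isfinite(res.Ees)
        assert res.es_method == "phase"

    def test_requires_two_levels(self, ramp_trace_27):
        single = ramp_trace_27.split_by_level()[0]
        with pytest.raises(ValueError, match="2 distinct preload levels"):
            analyze_ramp(single)
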