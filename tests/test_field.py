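"""Field-potential measurement, I-O curves, paired-pulse ratios, trains,
plasticity time courses and fiber-volley trajectories."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hand_stepped_stp
from hippoquant import field
from hippoquant.errors import UndefinedRatioError, UnstableBaselineWarning
from hippoquant.field import (MeasureConfig, analyze_train, fv_trajectory,
                              io_curve, measure_sweep, paired_pulse_ratio,
                              plasticity_quantify, ppr_series_summary,
                              tuning_curve)
from hippoquant.synth import (FieldKinetics, STPParams, fpsp_kernel,
                              simulate_fv_series,
                              simulate_plasticity_timecourse,
                              simulate_stp_train, stp_amplitudes_isi,
                              synthesize_field_sweeps)
from hippoquant.trace import FieldSweep, ProtocolSpec


class TestMeasureSweep:
    def test_noise_free_sweep_recovers_generator_truth(self, kinetics):
        proto = ProtocolSpec("baseline", {"frequency_hz": 0.1})
        (sw,) = synthesize_field_sweeps([1.0], kinetics, proto, 0)
        m = measure_sweep(sw)[0]
        assert m.fv_amp == pytest.approx(sw.landmarks[0]["fv_amp"], abs=0.005)
        assert m.fpsp_amp == pytest.approx(sw.landmarks[0]["fpsp_amp"],
                                           abs=0.01)

    def test_linear_rising_phase_slope_independent_of_bounds(self):
        """A linear 1 mV/ms descent gives slope 1.0 for any 20–80 window."""
        dt = 5e-5
        v = np.zeros(4000)
        k0 = 1200  # stimulus at 60 ms
        ramp = np.arange(400) * dt * 1000.0  # 1 mV/ms for 20 ms
        v[k0 + 100:k0 + 500] = -ramp
        v[k0 + 500:] = -ramp[-1]
        sw = FieldSweep(dt=dt, v=v, stim_times=[k0 * dt])
        m = measure_sweep(sw, MeasureConfig(fpsp_window_ms=(2.5, 30.0)))[0]
        assert m.fpsp_slope == pytest.approx(1.0, rel=1e-3)

    def test_slope_matches_dense_oracle_on_kernel(self, kinetics):
        """20–80% slope of the difference-of-exponentials fPSP within 1% of
        a dense-grid least-squares oracle on the closed-form kernel."""
        proto = ProtocolSpec("baseline", {"frequency_hz": 0.1})
        (sw,) = synthesize_field_sweeps([1.0], kinetics, proto, 0)
        m = measure_sweep(sw)[0]
        # oracle: closed-form kernel at 1 µs resolution
        t = np.arange(0, 30.0, 1e-3)
        y = 1.5 * fpsp_kernel(t, kinetics)
        peak = y.max()
        sel = (y >= 0.2 * peak) & (y <= 0.8 * peak) & (t <= t[np.argmax(y)])
        oracle = np.polyfit(t[sel], y[sel], 1)[0]
        assert m.fpsp_slope == pytest.approx(oracle, rel=0.01)

    @given(offset=st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=20)
    def test_slope_invariant_to_vertical_offset(self, offset, kinetics):
        proto = ProtocolSpec("baseline", {"frequency_hz": 0.1})
        (sw,) = synthesize_field_sweeps([1.0], kinetics, proto, 0)
        shifted = FieldSweep(dt=sw.dt, v=sw.v + offset,
                             stim_times=sw.stim_times)
        a = measure_sweep(sw)[0].fpsp_slope
        b = measure_sweep(shifted)[0].fpsp_slope
        assert a == pytest.approx(b, rel=1e-9)


class TestIOCurve:
    @staticmethod
    def _sigmoid_sweeps(kinetics, intensities):
        amax, i0, s = 2.0, 150.0, 40.0
        proto = ProtocolSpec("baseline", {"frequency_hz": 0.1})
        sweeps = []
        for i_ua in intensities:
            rel = amax / (1.0 + np.exp(-(i_ua - i0) / s)) / 1.5
            (sw,) = synthesize_field_sweeps([rel], kinetics, proto, 0)
            sw.stim_intensity = i_ua
            sweeps.append(sw)
        return sweeps, (amax, i0, s)

    def test_half_point_within_2pct_of_analytic_inverse(self, kinetics):
        intensities = np.arange(20.0, 401.0, 20.0)
        sweeps, (amax, i0, s) = self._sigmoid_sweeps(kinetics, intensities)
        curve = io_curve(sweeps)
        got = curve.intensity_for_fraction(0.5)
        target = 0.5 * curve.amplitudes.max()
        analytic = i0 - s * np.log(amax / target - 1.0)
        assert got == pytest.approx(analytic, rel=0.02)

    def test_fraction_one_returns_intensity_of_max(self, kinetics):
        intensities = np.arange(50.0, 260.0, 50.0)
        sweeps, _ = self._sigmoid_sweeps(kinetics, intensities)
        curve = io_curve(sweeps)
        assert curve.intensity_for_fraction(1.0) == intensities[-1]

    def test_interpolation_between_two_points(self):
        curve = field.IOCurve(intensities=np.array([100.0, 200.0]),
                              amplitudes=np.array([1.0, 2.0]))
        assert curve.intensity_for_fraction(0.75) == pytest.approx(150.0)

    def test_too_few_intensities_rejected(self, kinetics):
        sweeps, _ = self._sigmoid_sweeps(kinetics, [100.0, 200.0, 300.0])
        with pytest.raises(ValueError):
            io_curve(sweeps)


class TestPairedPulse:
    def test_double_amplitude_gives_ratio_two(self, kinetics):
        proto = ProtocolSpec("paired_pulse", {"isi_ms": 300.0})
        (sw,) = synthesize_field_sweeps([1.0, 2.0], kinetics, proto, 0)
        assert paired_pulse_ratio(sw) == pytest.approx(2.0, rel=1e-3)

    def test_short_isi_ppr_matches_recurrence_oracle(self, kinetics,
                                                     template_config):
        """U 0.2 / tau_f 200 / tau_d 500 at ISI 50 ms: PPR ≈ 1.33 within
        2% of the hand-stepped recurrence."""
        amps = stp_amplitudes_isi(STPParams(U=0.2, tau_f=200.0, tau_d=500.0),
                                  50.0, 2)
        proto = ProtocolSpec("paired_pulse", {"isi_ms": 50.0})
        (sw,) = synthesize_field_sweeps(amps, kinetics, proto, 0)
        ppr = paired_pulse_ratio(sw, template_config)
        oracle = hand_stepped_stp(0.2, 200.0, 500.0, 50.0, 2)[1]
        assert ppr == pytest.approx(oracle, rel=0.02)
        assert ppr == pytest.approx(1.33, abs=0.03)

    def test_first_response_below_floor_is_undefined(self, kinetics):
        proto = ProtocolSpec("paired_pulse", {"isi_ms": 300.0})
        (sw,) = synthesize_field_sweeps([1.0, 1.0], kinetics, proto, 0)
        cfg = MeasureConfig(min_amp_mv=5.0)
        with pytest.raises(UndefinedRatioError):
            paired_pulse_ratio(sw, cfg)

    def test_series_summary_last20_over_first(self):
        assert ppr_series_summary([2.0] + [1.5] * 20) == pytest.approx(0.75)

    @given(u=st.floats(0.05, 0.3))
    @settings(deadline=None, max_examples=20)
    def test_model_ppr_direction_facilitating_vs_depressing(self, u):
        """PPR > 1 for small U with slow facilitation decay; PPR < 1 as
        U -> 1 (checked against the recurrence oracle)."""
        fac = stp_amplitudes_isi(STPParams(U=u, tau_f=500.0, tau_d=200.0),
                                 50.0, 2)[1]
        dep = stp_amplitudes_isi(STPParams(U=1.0, tau_f=500.0, tau_d=2000.0),
                                 50.0, 2)[1]
        assert fac > 1.0 > dep
        assert fac == pytest.approx(
            hand_stepped_stp(u, 500.0, 200.0, 50.0, 2)[1], rel=1e-9)


class TestTrains:
    def test_flat_train_is_100_percent(self):
        res = analyze_train(np.full(100, 1.5), baseline=1.5)
        np.testing.assert_allclose(res.trajectory_pct, 100.0)
        assert res.last10_mean_pct == pytest.approx(100.0)

    def test_facilitating_render_recovers_model_plateau(self, kinetics,
                                                        template_config):
        params = STPParams(U=0.15, tau_f=800.0, tau_d=300.0)
        amps = simulate_stp_train(params, 5.0, 100)
        proto = ProtocolSpec("train", {"frequency_hz": 5.0, "n_pulses": 100})
        (sw,) = synthesize_field_sweeps(amps, kinetics, proto, 0)
        meas = [m.fpsp_amp for m in measure_sweep(sw, template_config)]
        res = analyze_train(meas, baseline=1.5, frequency_hz=5.0)
        model_last10 = amps[-10:].mean() * 100.0
        assert res.last10_mean_pct == pytest.approx(model_last10, rel=0.02)

    def test_depressing_100hz_train_falls_below_baseline(self, kinetics,
                                                         template_config):
        params = STPParams(U=0.9, tau_f=200.0, tau_d=2000.0)
        amps = simulate_stp_train(params, 100.0, 100)
        proto = ProtocolSpec("train", {"frequency_hz": 100.0,
                                       "n_pulses": 100})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (sw,) = synthesize_field_sweeps(amps, kinetics, proto, 0)
        meas = [m.fpsp_amp for m in measure_sweep(sw, template_config)]
        res = analyze_train(meas, baseline=1.5, frequency_hz=100.0)
        assert res.last10_mean_pct < 100.0
        assert np.all(np.diff(res.trajectory_pct[:5]) < 0)

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            analyze_train([1.0, 1.1], baseline=0.0)


class TestTuningCurve:
    def test_single_flat_train(self):
        res = analyze_train(np.full(100, 1.0), baseline=1.0, frequency_hz=5.0)
        curve = tuning_curve([res])
        assert curve.max_pct[0] == pytest.approx(100.0)

    def test_bandpass_peak_matches_recurrence_argmax(self):
        """Slowly decaying facilitation with fast-recovering depression
        (tau_f 800 ms, tau_d 100 ms) across 1–100 Hz: the tuning curve is
        band-pass and its peak frequency equals the recurrence oracle's
        argmax."""
        params = STPParams(U=0.1, tau_f=800.0, tau_d=100.0)
        freqs = [1.0, 5.0, 10.0, 20.0, 100.0]
        results = [analyze_train(simulate_stp_train(params, f, 100),
                                 baseline=1.0, frequency_hz=f)
                   for f in freqs]
        curve = tuning_curve(results)
        oracle_max = [hand_stepped_stp(0.1, 800.0, 100.0, 1000.0 / f,
                                       100).max() * 100.0 for f in freqs]
        assert (curve.frequencies[np.argmax(curve.max_pct)]
                == freqs[int(np.argmax(oracle_max))])
        # band-pass shape: interior maximum
        assert np.argmax(curve.max_pct) not in (0, len(freqs) - 1)

    def test_duplicate_frequency_rejected(self):
        res = analyze_train(np.full(10, 1.0), baseline=1.0, frequency_hz=5.0)
        with pytest.raises(ValueError, match="duplicate"):
            tuning_curve([res, res])


class TestPlasticityQuantify:
    EPOCHS = {"baseline": (-10.0, 0.0), "followup": (0.0, 60.0)}

    def test_baseline_normalizes_to_100_exactly(self):
        t, y = simulate_plasticity_timecourse(1.0, 0.86, 5.0)
        tc = plasticity_quantify(t, y, self.EPOCHS, {"w": (51.0, 60.0)})
        base = tc.normalized_pct[(tc.t_min >= -10) & (tc.t_min < 0)]
        assert base.mean() == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("post,window,expect", [
        (1.9, (51.0, 60.0), 190.0),    # LTP-like
        (0.86, (51.0, 60.0), 86.0),    # LTD-like
        (1.0, (41.0, 50.0), 100.0),    # flat / failed modulation
    ])
    def test_window_means_track_generator_truth(self, post, window, expect):
        t, y = simulate_plasticity_timecourse(1.0, post, 5.0)
        tc = plasticity_quantify(t, y, self.EPOCHS, {"w": window})
        assert tc.window_means["w"][0] == pytest.approx(expect, rel=0.02)

    def test_drifting_baseline_is_flagged(self):
        t = np.arange(-10.0, 60.0, 1.0 / 6.0)
        y = np.where(t < 0, 1.0 + 0.02 * t, 1.0)  # 12%/10 min drift
        with pytest.warns(UnstableBaselineWarning):
            tc = plasticity_quantify(t, y, self.EPOCHS, {"w": (51.0, 60.0)})
        assert not tc.baseline_stable

    def test_window_outside_followup_rejected(self):
        t, y = simulate_plasticity_timecourse(1.0, 1.9, 5.0)
        with pytest.raises(ValueError, match="follow-up"):
            plasticity_quantify(t, y, self.EPOCHS, {"w": (55.0, 70.0)})


class TestFvTrajectory:
    EPOCHS = {"baseline": (-10.0, 0.0)}
    WINDOWS = {"lfs_last5": (10.0, 15.0), "post_35_40": (50.0, 55.0)}

    def test_constant_fv_is_flat_100(self):
        t = np.arange(-10.0, 55.0, 1.0 / 6.0)
        res = fv_trajectory(t, np.full(t.size, 0.5), self.EPOCHS,
                            self.WINDOWS)
        np.testing.assert_allclose(res.normalized_pct, 100.0)

    def test_suppression_and_recovery_windows_match_truth(self):
        """FV dropping to 33% during LFS, recovering to 91%: window
        summaries within 2% of the generator truth."""
        t, fv = simulate_fv_series(0.33, 0.91, lfs_min=15.0,
                                   followup_min=40.0)
        res = fv_trajectory(t, 0.5 * fv, self.EPOCHS, self.WINDOWS)
        assert res.window_means["lfs_last5"][0] == pytest.approx(33.0,
                                                                 rel=0.02)
        assert res.window_means["post_35_40"][0] == pytest.approx(91.0,
                                                                  rel=0.02)

    def test_below_floor_sweeps_excluded_and_counted(self):
        t = np.arange(-10.0, 55.0, 1.0 / 6.0)
        fv = np.full(t.size, 0.5)
        fv[100:105] = 0.001
        res = fv_trajectory(t, fv, self.EPOCHS, self.WINDOWS,
                            noise_floor_mv=0.05)
        assert res.epochs["n_excluded"] == 5

    def test_all_flagged_series_is_an_error(self):
        t = np.arange(-10.0, 55.0, 1.0 / 6.0)
        with pytest.raises(UndefinedRatioError):
            fv_trajectory(t, np.zeros(t.size), self.EPOCHS, self.WINDOWS,
                          noise_floor_mv=0.05)
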