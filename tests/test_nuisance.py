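"""Respiration preprocessing, sniff metrics, FD and motion-task coupling."""

import numpy as np
import pytest

import mebold as mb


def sine_trace(fs=50.0, dur=400.0, f=0.3, amp=1.0):
    t = np.arange(0, dur, 1 / fs)
    return t, amp * np.sin(2 * np.pi * f * t)


class TestPreprocessRespiration:
    def test_output_one_value_per_volume_and_standardized(self):
        t, x = sine_trace()
        trace = mb.RespiratoryTrace(x, 50.0)
        reg = mb.preprocess_respiration(trace, tr_s=2.0, n_volumes=200)
        assert reg.shape == (200,)
        assert abs(reg.mean()) < 0.05
        assert reg.std() == pytest.approx(1.0, rel=0.1)

    def test_drift_attenuated_relative_to_breathing_band(self):
        fs, dur = 50.0, 600.0
        t = np.arange(0, dur, 1 / fs)
        breath = np.sin(2 * np.pi * 0.3 * t)
        drift = np.sin(2 * np.pi * 0.01 * t)
        trace = mb.RespiratoryTrace(breath + drift, fs)
        reg_full = mb.preprocess_respiration(trace, tr_s=0.5, n_volumes=1100)
        t_mid = (np.arange(1100) + 0.5) * 0.5
        # project the regressor onto each component
        def amp(f):
            c = np.cos(2 * np.pi * f * t_mid)
            s = np.sin(2 * np.pi * f * t_mid)
            return np.hypot(reg_full @ c, reg_full @ s) / (0.5 * t_mid.size)
        assert amp(0.01) / amp(0.3) < 0.1  # > 90% relative attenuation

    def test_constant_trace_rejected(self):
        trace = mb.RespiratoryTrace(np.full(1000, 3.0), 50.0)
        with pytest.raises(ValueError, match="variance"):
            mb.preprocess_respiration(trace, tr_s=2.0, n_volumes=5)

    def test_low_sampling_rate_rejected(self):
        trace = mb.RespiratoryTrace(np.arange(10.0), 1.0)
        with pytest.raises(ValueError, match="sampling"):
            mb.preprocess_respiration(trace, tr_s=2.0, n_volumes=3)


class TestSniffMetrics:
    def test_triangle_definition(self):
        fs = 100.0
        t = np.arange(0, 3, 1 / fs)
        x = np.interp(t, [0.0, 0.5, 1.5, 3.0], [0.0, 1.0, -0.5, 0.0])
        trace = mb.RespiratoryTrace(x, fs)
        vol, dur = mb.sniff_metrics(trace, (0.0, 2.0))
        assert vol == pytest.approx(1.5, abs=0.02)
        assert dur == pytest.approx(1.0, abs=0.02)

    def test_constant_window_zero_metrics(self):
        trace = mb.RespiratoryTrace(np.ones(500), 100.0)
        vol, dur = mb.sniff_metrics(trace, (0.0, 2.0))
        assert vol == 0.0 and dur == 0.0

    def test_recovers_injected_extremes(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        x = 0.05 * rng.normal(size=400)
        x[120] = 2.0   # peak at 1.2 s
        x[250] = -1.0  # trough at 2.5 s
        trace = mb.RespiratoryTrace(x, fs)
        vol, dur = mb.sniff_metrics(trace, (0.0, 4.0))
        assert vol == pytest.approx(3.0, abs=0.01)
        assert dur == pytest.approx(1.3, abs=0.01)

    def test_window_outside_trace_rejected(self):
        trace = mb.RespiratoryTrace(np.ones(500), 100.0)
        with pytest.raises(ValueError):
            mb.sniff_metrics(trace, (100.0, 102.0))


class TestFramewiseDisplacement:
    def test_static_is_zero(self):
        assert np.all(mb.framewise_displacement(np.zeros((10, 6))) == 0)

    def test_translation_step(self):
        p = np.zeros((10, 6))
        p[5:, 0] = 1.0
        fd = mb.framewise_displacement(p)
        assert fd[5] == 1.0
        assert fd[4] == 0.0 and fd[6] == 0.0

    def test_rotation_step_scaled_by_radius(self):
        p = np.zeros((10, 6))
        p[5:, 3] = 0.01
        fd = mb.framewise_displacement(p, radius_mm=50.0)
        assert fd[5] == pytest.approx(0.5)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            mb.framewise_displacement(np.zeros((10, 5)))


class TestFdTaskR2:
    def _events(self):
        return mb.make_event_table([20.0, 120.0, 220.0], [2.0] * 3, ["odor"] * 3)

    def test_linear_relation_gives_r2_one(self):
        events = self._events()
        reg = mb.simulate_task_timecourse(events, 2.0, 150, "odor")
        fd = 3.0 * reg + 5.0  # affine in the regressor, strictly positive
        motion = mb.MotionTrace(params=np.zeros((150, 6)), fd=fd)
        r2 = mb.fd_task_r2(motion, events, 2.0, "odor")
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_fd_gives_zero(self):
        events = self._events()
        reg = mb.simulate_task_timecourse(events, 2.0, 150, "odor")
        rng = np.random.default_rng(1)
        fd = rng.normal(size=150)
        regc = reg - reg.mean()
        fd_orth = fd - (fd - fd.mean()) @ regc / (regc @ regc) * regc
        fd_orth = fd_orth - fd_orth.min()  # shift positive; r is shift-invariant
        motion = mb.MotionTrace(params=np.zeros((150, 6)), fd=fd_orth)
        r2 = mb.fd_task_r2(motion, events, 2.0, "odor")
        assert r2 < 1e-20

    def test_white_noise_expectation(self):
        # E[R^2] = 1/(n-1) for independent noise against a fixed regressor
        events = self._events()
        n = 200
        reg = mb.simulate_task_timecourse(events, 2.0, n, "odor")
        rng = np.random.default_rng(2)
        fd = rng.normal(size=(10000, n))
        regc = (reg - reg.mean()) / np.linalg.norm(reg - reg.mean())
        fdc = fd - fd.mean(axis=1, keepdims=True)
        r = (fdc @ regc) / np.linalg.norm(fdc, axis=1)
        assert (r**2).mean() == pytest.approx(1.0 / (n - 1), rel=0.1)

    def test_zero_variance_rejected(self):
        events = self._events()
        motion = mb.MotionTrace(params=np.zeros((150, 6)), fd=np.zeros(150))
        with pytest.raises(ValueError):
            mb.fd_task_r2(motion, events, 2.0, "odor")
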