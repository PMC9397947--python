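"""Filtering, push segmentation and per-push variable integration."""

import math

import numpy as np
import pytest

from handrim.config import DetectionSettings, SimulationConfig
from handrim.errors import DataError
from handrim.kinetics import (ErgometerSignal, aggregate_session,
                              compute_push_metrics, detect_pushes,
                              extract_pushes, filter_signal)
from handrim.synthetic import friction_force, simulate_ergometer_block

FS = 100.0


def make_signal(force, velocity=None, fs=FS, side="left", r=0.355):
    n = len(force)
    v = np.full(n, 2.78) if velocity is None else velocity
    return ErgometerSignal(np.arange(n) / fs, np.asarray(force, float), v,
                           side=side, wheel_radius=r)


def half_sine_pulse(peak_force, duration, fs=FS, pad=2.0):
    n_pad = int(pad * fs)
    n_p = int(duration * fs) + 1
    pulse = peak_force * np.sin(np.pi * np.arange(n_p) / (n_p - 1))
    return np.concatenate([np.zeros(n_pad), pulse, np.zeros(n_pad)])


class TestFilter:
    def test_dc_gain_unity(self):
        sig = make_signal(np.full(500, 10.0))
        out = filter_signal(sig)
        assert np.allclose(out.force, 10.0, atol=1e-9)

    @pytest.mark.parametrize("freq,max_atten,min_atten", [
        (1.0, 1e-3, 0.0),    # passband: < 0.1% amplitude loss
        (40.0, 1.0, 0.99),   # stopband: > 99% attenuation
    ])
    def test_analytic_butterworth_magnitude(self, freq, max_atten, min_atten):
        """Forward-backward 4th order has |H|^2 = 1/(1+(f/fc)^8) magnitude;
        measured sine attenuation must straddle the analytic value."""
        t = np.arange(3000) / FS
        sig = make_signal(np.sin(2 * np.pi * freq * t))
        out = filter_signal(sig, cutoff=15.0, order=4)
        core = slice(500, 2500)  # avoid edge transients
        ratio = np.std(out.force[core]) / np.std(sig.force[core])
        analytic = 1.0 / (1.0 + (freq / 15.0) ** 8)
        assert min_atten <= 1.0 - ratio <= max_atten
        assert ratio == pytest.approx(analytic, abs=5e-3)

    def test_zero_phase_no_peak_lag(self):
        force = half_sine_pulse(30.0, 0.2)
        sig = make_signal(force)
        out = filter_signal(sig)
        assert abs(int(np.argmax(out.force)) - int(np.argmax(force))) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        sig = make_signal(np.zeros(500))
        with pytest.raises(DataError, match="Nyquist"):
            filter_signal(sig, cutoff=50.0)

    def test_non_uniform_time_rejected(self):
        t = np.arange(500) / FS
        t[100] += 0.004
        with pytest.raises(DataError, match="uniform"):
            ErgometerSignal(t, np.zeros(500), np.full(500, 1.0))


class TestDetection:
    def test_clean_block_count_matches_ground_truth(self, clean_block):
        left, _, truth = clean_block
        intervals = detect_pushes(filter_signal(left))
        assert len(intervals) == len(truth) == 60

    def test_all_zero_force_yields_no_pushes(self):
        sig = make_signal(np.zeros(2000))
        assert detect_pushes(sig) == []

    def test_single_pulse_onset_accuracy(self):
        """Threshold crossing of an isolated 0.2 s half-sine must land within
        0.02 s of the true onset (analytic: crossing at asin(thr/peak)/pi*t_p)."""
        force = half_sine_pulse(30.0, 0.2)
        sig = make_signal(force)
        intervals = detect_pushes(filter_signal(sig))
        assert len(intervals) == 1
        true_start = 2.0
        assert abs(intervals[0][0] - true_start) <= 0.02
        assert abs(intervals[0][1] - (true_start + 0.2)) <= 0.02

    def test_lower_threshold_never_decreases_count(self, noisy_block):
        left, _, _ = noisy_block
        filt = filter_signal(left)
        counts = [len(detect_pushes(filt, threshold=thr))
                  for thr in (8.0, 5.0, 3.0, 2.0, 1.0)]
        assert counts == sorted(counts)

    def test_noisy_block_still_recovers_count(self, noisy_block):
        left, _, truth = noisy_block
        assert len(detect_pushes(filter_signal(left))) == len(truth)


class TestPushMetrics:
    def test_constant_power_work_rectangle(self):
        # 50 W for 0.2 s -> 10 J; force = 50/2.78 N at 2.78 m/s
        sig = make_signal(np.full(500, 50.0 / 2.78))
        p = compute_push_metrics(sig, (1.0, 1.2))
        assert p.work == pytest.approx(10.0, rel=1e-9)
        assert p.mean_power == pytest.approx(50.0, rel=1e-9)

    def test_contact_angle_from_constant_velocity(self):
        """(2.78/0.355) rad/s * 0.20 s = 89.74 degrees."""
        sig = make_signal(np.zeros(500))
        p = compute_push_metrics(sig, (1.0, 1.2))
        expected = math.degrees(2.78 / 0.355 * 0.20)
        assert p.contact_angle == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(89.74, abs=0.01)

    def test_half_sine_mean_torque_two_over_pi(self):
        peak_tau = 12.0
        force = half_sine_pulse(peak_tau / 0.355, 0.2)
        sig = make_signal(force)
        p = compute_push_metrics(sig, (2.0, 2.2))
        assert p.peak_torque == pytest.approx(peak_tau, rel=1e-6)
        assert p.mean_torque == pytest.approx(2 / math.pi * peak_tau, rel=5e-3)

    def test_interval_shorter_than_two_samples_rejected(self):
        sig = make_signal(np.zeros(500))
        with pytest.raises(DataError, match="2 samples"):
            compute_push_metrics(sig, (1.0, 1.004))

    def test_push_invariants_on_synthetic_data(self, clean_block):
        left, _, _ = clean_block
        pushes = extract_pushes(left)
        for p in pushes:
            assert 0 < p.push_time
            assert p.cycle_time is None or p.push_time <= p.cycle_time
            assert p.work >= 0
            assert p.peak_torque >= p.mean_torque >= 0
            assert p.peak_power >= p.mean_power >= 0
            assert p.contact_angle > 0


class TestParameterRecovery:
    def test_contact_angle_and_push_time_recovered_over_seeds(self):
        """Clean blocks across >= 20 seeds: contact angle within 3 degrees,
        push time within 0.02 s, counts exact."""
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, block_duration=30.0,
                                   noise_sd_force=0.0)
            left, _, truth = simulate_ergometer_block(cfg)
            pushes = extract_pushes(left)
            assert len(pushes) == len(truth)
            for p, tr in zip(pushes, truth):
                assert abs(p.contact_angle - tr["contact_angle"]) <= 3.0
                assert abs(p.push_time - tr["push_time"]) <= 0.02


class TestAggregation:
    def _session_blocks(self, n=3, seed=21, **kw):
        blocks = []
        for b in range(n):
            cfg = SimulationConfig(seed=seed + b, block_duration=120.0, **kw)
            left, right, _ = simulate_ergometer_block(cfg)
            blocks.append((left, right))
        return blocks

    def test_identical_blocks_mean_identity(self):
        cfg = SimulationConfig(seed=3, block_duration=120.0,
                               noise_sd_force=0.0)
        left, right, _ = simulate_ergometer_block(cfg)
        one = aggregate_session([(left, right)], session=1)
        three = aggregate_session([(left, right)] * 3, session=1)
        assert three.cycle_time == pytest.approx(one.cycle_time)
        assert three.work == pytest.approx(one.work)

    def test_block_mean_is_arithmetic_mean(self):
        """Blocks with distinct cycle times average arithmetically."""
        blocks = []
        for b, freq in enumerate((1.0, 1.0 / 1.2, 1.0 / 1.4)):
            cfg = SimulationConfig(seed=b, block_duration=120.0,
                                   push_frequency=freq, noise_sd_force=0.0)
            left, right, _ = simulate_ergometer_block(cfg)
            blocks.append((left, right))
        s = aggregate_session(blocks, session=1)
        assert s.cycle_time == pytest.approx(1.2, abs=0.01)

    def test_power_balance_two_work_over_cycle(self):
        """2 * side-mean work per push / cycle time matches the external
        friction power within 2% on noise-free data."""
        blocks = self._session_blocks(noise_sd_force=0.0)
        s = aggregate_session(blocks, session=1)
        po_pushes = 2.0 * s.work / s.cycle_time
        cfg = SimulationConfig()
        external = friction_force(cfg) * s.speed
        assert po_pushes == pytest.approx(external, rel=0.02)
        assert s.power == pytest.approx(external, rel=0.02)

    def test_empty_window_flagged_missing_not_zero(self):
        n = 12001
        t = np.arange(n) / FS
        quiet = ErgometerSignal(t, np.zeros(n), np.full(n, 2.78))
        s = aggregate_session([(quiet, quiet.replace(side="right"))],
                              session=1)
        assert math.isnan(s.work)
        assert any("no pushes" in m for m in s.missing)
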