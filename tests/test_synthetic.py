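"""Generator contracts: known ground truth, physical balance, determinism."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from handrim.config import SimulationConfig
from handrim.errors import ConfigError, DataError
from handrim.physiology import energy_expenditure
from handrim.synthetic import (balanced_peak_torque, friction_force,
                               simulate_ergometer_block,
                               simulate_hand_trajectory, simulate_spirometry)

G = 9.81


class TestErgometerBlock:
    def test_push_count_forced_by_construction(self):
        cfg = SimulationConfig(seed=0, block_duration=60.0,
                               push_frequency=1.0, noise_sd_force=0.0)
        _, _, truth = simulate_ergometer_block(cfg)
        assert len(truth) == 60

    @pytest.mark.parametrize("freq,duration,expected",
                             [(0.8, 60.0, 48), (1.25, 30.0, 37)])
    def test_push_count_floor_rule(self, freq, duration, expected):
        cfg = SimulationConfig(seed=0, push_frequency=freq,
                               block_duration=duration, noise_sd_force=0.0)
        _, _, truth = simulate_ergometer_block(cfg)
        assert len(truth) == expected == int(freq * duration)

    def test_balanced_pushes_hold_commanded_speed(self, clean_cfg, clean_block):
        """Friction-balanced pulses keep the long-run mean speed at target."""
        left, _, _ = clean_block
        assert left.velocity.mean() == pytest.approx(
            clean_cfg.target_speed, rel=0.01)

    def test_velocity_matches_independent_ode_integration(self, clean_cfg):
        """Cross-check the integrated wheel speed against an independent
        adaptive solver of m dv/dt = F_push(t) - mu*m*g."""
        cfg = clean_cfg
        left, right, _ = simulate_ergometer_block(cfg, duration=10.0)
        tau_pk = balanced_peak_torque(cfg)
        a = tau_pk / cfg.wheel_radius  # per-side peak force, symmetric
        t_p, cyc = cfg.push_time, cfg.cycle_time

        def f_total(t):
            ph = t % cyc
            return 2 * a * np.sin(np.pi * ph / t_p) if ph <= t_p else 0.0

        def rhs(t, v):
            return [(f_total(t) - friction_force(cfg)) / cfg.mass]

        sol = solve_ivp(rhs, (0, 10.0), [left.velocity[0]],
                        t_eval=left.time, max_step=cfg.push_time / 20,
                        rtol=1e-8, atol=1e-10)
        assert np.max(np.abs(sol.y[0] - left.velocity)) < 5e-3

    def test_energy_balance_at_steady_state(self, clean_block, clean_cfg):
        """Mean total instantaneous push power equals mu*m*g*mean(v) within 1%."""
        left, right, _ = clean_block
        p_push = np.mean(left.force * left.velocity
                         + right.force * right.velocity)
        p_fric = friction_force(clean_cfg) * left.velocity.mean()
        assert p_push == pytest.approx(p_fric, rel=0.01)

    def test_seed_determinism_bitwise(self):
        cfg = SimulationConfig(seed=5, block_duration=20.0)
        a = simulate_ergometer_block(cfg)
        b = simulate_ergometer_block(cfg)
        for s1, s2 in zip(a[:2], b[:2]):
            np.testing.assert_array_equal(s1.force, s2.force)
            np.testing.assert_array_equal(s1.velocity, s2.velocity)

    def test_speed_collapse_names_offending_parameter(self):
        cfg = SimulationConfig(seed=0, block_duration=60.0,
                               peak_torque_true=0.1)
        with pytest.raises(ConfigError, match="peak_torque_true"):
            simulate_ergometer_block(cfg)

    def test_truth_mean_torque_is_two_over_pi_peak(self, clean_block):
        _, _, truth = clean_block
        rec = truth[0]
        assert rec["mean_torque"] == pytest.approx(
            2 / np.pi * rec["peak_torque"])


class TestSimulationConfigInvariants:
    @pytest.mark.parametrize("kw", [
        {"rim_diameter": 0.8},              # rim >= wheel
        {"gme_true": 0.0}, {"gme_true": 120.0},
        {"rer_true": 0.5}, {"rer_true": 1.5},
        {"push_frequency": 0.001},          # no complete push in a block
        {"mass": -1.0},
        {"contact_angle_true": 300.0, "push_frequency": 2.0},  # push > cycle
    ])
    def test_non_physical_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw).validate()


class TestSpirometry:
    def test_block_mean_ee_forced_by_construction(self):
        """gme 5%, 21 W, zero noise -> EE = 21/0.05 = 420 W."""
        cfg = SimulationConfig(seed=1, gme_true=5.0, noise_sd_breath=0.0,
                               block_duration=120.0)
        sp = simulate_spirometry(cfg, 21.0)
        assert energy_expenditure(sp, (0.0, 120.0)) == pytest.approx(420.0,
                                                                     abs=1e-9)

    def test_zero_power_hits_resting_floor_not_zero(self):
        cfg = SimulationConfig(seed=1, noise_sd_breath=0.0,
                               block_duration=120.0)
        sp = simulate_spirometry(cfg, 0.0)
        assert energy_expenditure(sp, (0.0, 120.0)) == pytest.approx(100.0,
                                                                     rel=1e-6)

    def test_rer_true_sets_measured_rer(self):
        cfg = SimulationConfig(seed=1, rer_true=1.05, noise_sd_breath=0.0,
                               block_duration=120.0)
        sp = simulate_spirometry(cfg, 21.0)
        assert np.mean(sp.vco2) / np.mean(sp.vo2) == pytest.approx(1.05)

    def test_negative_power_rejected(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(DataError):
            simulate_spirometry(cfg, -1.0)

    def test_determinism(self):
        cfg = SimulationConfig(seed=9, block_duration=60.0)
        a = simulate_spirometry(cfg, 21.0)
        b = simulate_spirometry(cfg, 21.0)
        np.testing.assert_array_equal(a.vo2, b.vo2)
        np.testing.assert_array_equal(a.time, b.time)


class TestHandTrajectory:
    def test_sc_recovery_lies_below_rim(self, clean_cfg):
        from handrim.patterns import recovery_intervals, rim_deviation
        traj = simulate_hand_trajectory("SC", clean_cfg)
        eps = 0.05 * traj.rim_radius
        for a, b in recovery_intervals(traj):
            m = (traj.time > a + 0.05) & (traj.time < b - 0.05)
            dev = rim_deviation(traj.x[m], traj.y[m], traj.rim_radius)
            assert dev.max() < eps  # never above the band

    def test_arc_stays_within_band(self, clean_cfg):
        from handrim.patterns import rim_deviation
        traj = simulate_hand_trajectory("ARC", clean_cfg)
        dev = rim_deviation(traj.x, traj.y, traj.rim_radius)
        assert np.max(np.abs(dev)) <= 0.05 * traj.rim_radius + 1e-12

    def test_duration_and_push_intervals(self, clean_cfg):
        traj = simulate_hand_trajectory("DLOP", clean_cfg)
        assert traj.duration >= 15.0
        assert len(traj.push_intervals) >= 15

    def test_unknown_pattern_rejected(self, clean_cfg):
        with pytest.raises(DataError, match="unknown pattern"):
            simulate_hand_trajectory("LOOP", clean_cfg)
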