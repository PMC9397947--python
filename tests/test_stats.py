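"""Protocol physics and statistics: friction power, coast-down, compliance,
the mixed-effects learning model and the expert-comparison t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as spstats

from handrim.config import ProtocolConfig
from handrim.errors import DataError
from handrim.reference import NOVICE_MEANS
from handrim.stats import (athlete_comparison, coast_down_mu,
                           fit_learning_model, speed_compliance,
                           theoretical_power)


class TestTheoreticalPower:
    def test_study_load_rounds_to_21_w(self):
        p = theoretical_power(0.011, 69.3, 2.78)
        assert round(p) == 21
        assert p == pytest.approx(20.79, abs=0.01)

    def test_zero_speed_zero_power(self):
        assert theoretical_power(0.011, 69.3, 0.0) == 0.0

    @given(st.floats(1.0, 120.0), st.floats(0.1, 5.0))
    def test_linear_in_mass_and_speed(self, mass, speed):
        base = theoretical_power(0.011, mass, speed)
        assert theoretical_power(0.011, 2 * mass, speed) == pytest.approx(
            2 * base, rel=1e-12)
        assert theoretical_power(0.011, mass, 2 * speed) == pytest.approx(
            2 * base, rel=1e-12)


class TestCoastDown:
    def test_analytic_slope(self):
        t = np.linspace(0, 5, 501)
        v = 3.0 - 0.10791 * t
        assert coast_down_mu(t, v) == pytest.approx(0.011, rel=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 5, 501)
        for _ in range(20):
            v = 3.0 - 0.011 * 9.81 * t + rng.normal(0, 0.01, t.size)
            assert coast_down_mu(t, v) == pytest.approx(0.011, rel=0.05)

    def test_constant_velocity_rejected(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(DataError, match="not decreasing"):
            coast_down_mu(t, np.full(100, 2.0))

    def test_round_trip_with_simulated_coast_down(self):
        """mu -> simulate free deceleration -> recover mu exactly."""
        mu = 0.0137
        t = np.linspace(0, 3, 301)
        v = 2.8 - mu * 9.81 * t
        assert coast_down_mu(t, v) == pytest.approx(mu, rel=1e-9)


class TestSpeedCompliance:
    @pytest.mark.parametrize("speed,ok", [
        (2.78, True), (2.60, False), (2.95, False),
        (2.6411, True), (2.918, True), (2.92, False),
    ])
    def test_five_percent_band(self, speed, ok):
        assert speed_compliance(speed, ProtocolConfig()) is ok


def simulate_longitudinal(rng, n_subj=15, n_sess=9, beta_session=0.0,
                          u0_sd=1.0, u1_sd=0.05, e_sd=1.0, beta_speed=1.0):
    speeds = np.asarray(NOVICE_MEANS["speed"])
    rows = []
    for s in range(n_subj):
        u0 = rng.normal(0, u0_sd)
        u1 = rng.normal(0, u1_sd) if u1_sd > 0 else 0.0
        for k in range(1, n_sess + 1):
            sp = speeds[(k - 1) % 9] + rng.normal(0, 0.05)
            y = 10 + beta_session * k + beta_speed * sp + u0 + u1 * k \
                + (rng.normal(0, e_sd) if e_sd > 0 else 0.0)
            rows.append({"subject": s, "session": k, "speed": sp, "y": y})
    return pd.DataFrame(rows)


class TestLearningModel:
    def test_perfect_affine_fit_recovers_slope_exactly(self, rng):
        df = simulate_longitudinal(rng, beta_session=0.25, u0_sd=0, u1_sd=0,
                                   e_sd=0, beta_speed=0.0)
        res = fit_learning_model(df, "y")
        assert res.degenerate
        assert res.slope_session == pytest.approx(0.25, abs=1e-9)
        assert res.p == 0.0

    def test_slope_recovery_with_noise(self, rng):
        """Mean slope estimate across simulations within 10% of the true
        practice effect (0.2 per session at unit residual SD)."""
        errs = []
        for _ in range(30):
            df = simulate_longitudinal(rng, beta_session=0.2)
            res = fit_learning_model(df, "y")
            errs.append(res.slope_session - 0.2)
        assert abs(np.mean(errs)) < 0.02

    def test_strong_effect_detected(self, rng):
        df = simulate_longitudinal(rng, beta_session=0.3)
        res = fit_learning_model(df, "y")
        assert res.chi2 > 3.84 and res.p < 0.05
        assert res.slope_session > 0

    def test_lrt_invariant_under_affine_outcome_rescaling(self, rng):
        df = simulate_longitudinal(rng, beta_session=0.15)
        res1 = fit_learning_model(df, "y")
        df2 = df.assign(y=3.7 * df["y"] + 11.0)
        res2 = fit_learning_model(df2, "y")
        assert res1.chi2 >= 0
        assert res2.chi2 == pytest.approx(res1.chi2, abs=0.05)

    def test_missing_outcome_rows_dropped(self, rng):
        df = simulate_longitudinal(rng, beta_session=0.3)
        df.loc[df.index[:5], "y"] = np.nan
        res = fit_learning_model(df, "y")
        assert res.n_obs == len(df) - 5

    def test_too_few_subjects_rejected(self, rng):
        df = simulate_longitudinal(rng, n_subj=1)
        with pytest.raises(DataError):
            fit_learning_model(df, "y")


class TestAthleteComparison:
    @pytest.mark.parametrize("mean,sd,ref,expected_t,expected_p", [
        (1.26, 0.39, 1.26, 0.00, 0.50),    # cycle time row
        (5.39, 0.60, 6.66, -8.20, None),   # efficiency row
        (11.4, 1.60, 8.00, 8.20, None),    # perceived-exertion row
        (7.73, 1.87, 6.17, 3.22, None),    # mean torque row
    ])
    def test_reference_session9_t_statistics(self, mean, sd, ref,
                                             expected_t, expected_p):
        res = athlete_comparison(mean=mean, sd=sd, n=15, ref=ref)
        assert res.t == pytest.approx(expected_t, rel=0.01, abs=1e-12)
        if expected_p is not None:
            assert res.p == pytest.approx(expected_p, abs=1e-9)
        assert res.df == 14

    @given(st.floats(-5, 5), st.floats(0.1, 3), st.integers(3, 30))
    def test_mean_equal_ref_gives_zero_t(self, mean, sd, n):
        res = athlete_comparison(mean=mean, sd=sd, n=n, ref=mean)
        assert res.t == 0.0 and res.p == 0.5

    def test_raw_values_match_summary_path(self, rng):
        vals = rng.normal(5.0, 0.7, 15)
        a = athlete_comparison(vals, ref=6.66)
        b = athlete_comparison(mean=float(np.mean(vals)),
                               sd=float(np.std(vals, ddof=1)), n=15, ref=6.66)
        assert a.t == pytest.approx(b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_agrees_with_scipy_two_sided(self, rng):
        vals = rng.normal(5.0, 0.7, 15)
        ours = athlete_comparison(vals, ref=6.0, sided="two")
        ref = spstats.ttest_1samp(vals, 6.0)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_sd_infinite_t(self):
        res = athlete_comparison(mean=5.0, sd=0.0, n=10, ref=4.0)
        assert math.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(DataError):
            athlete_comparison([5.0], ref=4.0)
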