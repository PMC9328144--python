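import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gutsred import (
    DamageTrajectory,
    ExposureProfile,
    ITParams,
    SDParams,
    SurvivalCurve,
    constant_profile,
    damage,
    simulate_survivors,
    survival_it,
    survival_sd,
)
from gutsred.guts_core import it_survival_constant, sd_survival_constant

from conftest import random_piecewise_profile


class TestParams:
    def test_sd_invariants(self):
        with pytest.raises(ValueError):
            SDParams(kD=0.0, zw=1, bw=1, hb=0)
        with pytest.raises(ValueError):
            SDParams(kD=1, zw=-1, bw=1, hb=0)

    def test_it_invariants(self):
        with pytest.raises(ValueError):
            ITParams(kD=1, mw=0.0, beta=2, hb=0)
        with pytest.raises(ValueError):
            ITParams(kD=1, mw=1, beta=-2, hb=0)


class TestDamage:
    def test_constant_exposure_half_saturation(self):
        traj = damage(constant_profile(10.0, 5.0), kD=1.0, eval_times=[math.log(2)])
        assert traj.value_at(math.log(2)) == pytest.approx(5.0, rel=1e-12)

    def test_steady_state(self):
        traj = damage(constant_profile(10.0, 25.0), kD=1.0, eval_times=[20.0])
        assert traj.value_at(20.0) == pytest.approx(10.0, abs=1e-6)

    def test_linearity_in_exposure(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_piecewise_profile(rng)
            kD = 10 ** rng.uniform(-1, 1.5)
            t1 = damage(p, kD)
            t2 = damage(p.scale(2.0), kD)
            np.testing.assert_allclose(
                t2.value_at(t1.times), 2.0 * t1.damage, rtol=1e-10, atol=1e-12
            )

    def test_matches_numeric_ode_oracle(self):
        # small version of the full randomized-oracle sweep in the
        # acceptance suite
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = random_piecewise_profile(rng)
            kD = 10 ** rng.uniform(-1, 1.5)
            eval_t = np.sort(rng.uniform(0, p.t_end, 9))
            traj = damage(p, kD, eval_times=eval_t)
            sol = solve_ivp(
                lambda t, y: [kD * (p.at(t) - y[0])],
                (0, p.t_end), [0.0], t_eval=eval_t,
                rtol=1e-11, atol=1e-13, max_step=float(np.diff(p.times).min()),
            )
            np.testing.assert_allclose(
                traj.value_at(eval_t), sol.y[0], rtol=1e-6, atol=1e-9
            )

    def test_running_max_non_decreasing_and_exact_on_pulse(self):
        # triangular pulse then zero: running max must freeze at the peak
        p = ExposureProfile(np.array([0.0, 1.0, 2.0, 4.0]),
                            np.array([0.0, 10.0, 0.0, 0.0]))
        traj = damage(p, kD=2.0, eval_times=np.linspace(0, 4, 33))
        assert np.all(np.diff(traj.running_max) >= 0)
        assert traj.running_max[-1] == pytest.approx(np.max(traj.damage))
        # damage keeps decaying after the pulse, the running max does not
        assert traj.damage[-1] < traj.running_max[-1]

    def test_invalid_inputs(self):
        p = constant_profile(1.0, 2.0)
        with pytest.raises(ValueError):
            damage(p, kD=-1.0)
        with pytest.raises(ValueError):
            damage(p, kD=1.0, eval_times=[3.0])


class TestSurvivalSD:
    def test_constant_excess_hazard_hand_integral(self):
        t = np.linspace(0.0, 2.0, 9)
        traj = DamageTrajectory(t, np.full(t.size, 10.0), np.full(t.size, 10.0))
        S = survival_sd(traj, SDParams(kD=1, zw=4.0, bw=0.1, hb=0.0))
        assert S.survival[-1] == pytest.approx(math.exp(-1.2), rel=1e-9)

    def test_below_threshold_background_only(self):
        p = constant_profile(1.0, 3.0)
        traj = damage(p, kD=1.0, eval_times=np.linspace(0, 3, 7))
        S = survival_sd(traj, SDParams(kD=1, zw=5.0, bw=2.0, hb=0.05))
        np.testing.assert_allclose(S.survival, np.exp(-0.05 * S.times), rtol=1e-9)

    def test_zero_killing_rate_background_only(self):
        p = constant_profile(50.0, 3.0)
        traj = damage(p, kD=1.0, eval_times=np.linspace(0, 3, 7))
        S = survival_sd(traj, SDParams(kD=1, zw=0.0, bw=0.0, hb=0.02))
        np.testing.assert_allclose(S.survival, np.exp(-0.02 * S.times), rtol=1e-9)

    def test_agrees_with_constant_closed_form(self):
        # general trapezoid path vs the exact constant-exposure formula
        p = SDParams(kD=0.8, zw=1.5, bw=0.4, hb=0.01)
        times = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        for c in (0.0, 1.0, 3.0, 12.0):
            traj = damage(constant_profile(c, 4.0), p.kD, eval_times=times)
            general = survival_sd(traj, p).at(times)
            closed = sd_survival_constant([c], times, p)[0]
            np.testing.assert_allclose(general, closed, rtol=1e-5, atol=1e-9)

    def test_non_increasing_and_monotone_in_exposure(self):
        rng = np.random.default_rng(3)
        p = SDParams(kD=1.2, zw=2.0, bw=0.5, hb=0.01)
        prof = random_piecewise_profile(rng)
        times = np.linspace(0, prof.t_end, 11)
        S1 = survival_sd(damage(prof, p.kD, eval_times=times), p).at(times)
        S2 = survival_sd(damage(prof.scale(1.5), p.kD, eval_times=times), p).at(times)
        assert np.all(np.diff(S1) <= 1e-12)
        assert np.all(S2 <= S1 + 1e-12)


class TestSurvivalIT:
    def test_median_threshold_gives_half_survival(self):
        t = np.array([0.0, 1.0, 2.0])
        mw = 3.0
        traj = DamageTrajectory(t, np.array([0.0, mw, mw]), np.array([0.0, mw, mw]))
        S = survival_it(traj, ITParams(kD=1, mw=mw, beta=2.5, hb=0.1))
        np.testing.assert_allclose(
            S.survival[1:], 0.5 * np.exp(-0.1 * t[1:]), rtol=1e-12
        )

    def test_zero_exposure_background_only(self):
        t = np.linspace(0, 4, 5)
        traj = DamageTrajectory(t, np.zeros(5), np.zeros(5))
        S = survival_it(traj, ITParams(kD=1, mw=2, beta=2, hb=0.03))
        np.testing.assert_allclose(S.survival, np.exp(-0.03 * t), rtol=1e-12)

    def test_loglogistic_plugin_value(self):
        t = np.array([0.0, 1.0])
        traj = DamageTrajectory(t, np.array([0.0, 4.0]), np.array([0.0, 4.0]))
        S = survival_it(traj, ITParams(kD=1, mw=2.0, beta=2.0, hb=0.0))
        assert S.survival[-1] == pytest.approx(0.2, rel=1e-12)

    def test_agrees_with_constant_closed_form(self):
        p = ITParams(kD=0.8, mw=2.5, beta=3.0, hb=0.01)
        times = np.array([0.0, 1.0, 2.0, 4.0])
        for c in (0.0, 1.0, 3.0, 12.0):
            traj = damage(constant_profile(c, 4.0), p.kD, eval_times=times)
            general = survival_it(traj, p).at(times)
            closed = it_survival_constant([c], times, p)[0]
            np.testing.assert_allclose(general, closed, rtol=1e-9, atol=1e-12)

    def test_zero_exposure_sd_equals_it(self):
        # both variants reduce to pure background survival without exposure
        t = np.linspace(0, 4, 9)
        traj = DamageTrajectory(t, np.zeros(9), np.zeros(9))
        S_sd = survival_sd(traj, SDParams(kD=1, zw=1, bw=1, hb=0.02))
        S_it = survival_it(traj, ITParams(kD=1, mw=1, beta=2, hb=0.02))
        np.testing.assert_allclose(S_sd.survival, S_it.survival, rtol=1e-9)


class TestSimulate:
    def test_certain_survival(self):
        t = np.array([0.0, 1.0, 2.0])
        curve = SurvivalCurve(t, np.ones(3))
        np.testing.assert_array_equal(simulate_survivors(curve, 40, t, 0), [40, 40, 40])

    def test_certain_death_at_end(self):
        t = np.array([0.0, 1.0, 2.0])
        curve = SurvivalCurve(t, np.array([1.0, 0.5, 0.0]))
        assert simulate_survivors(curve, 40, t, 0)[-1] == 0

    def test_seed_reproducibility(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        curve = SurvivalCurve(t, np.array([1.0, 0.8, 0.5, 0.3]))
        a = simulate_survivors(curve, 40, t, 123)
        b = simulate_survivors(curve, 40, t, 123)
        np.testing.assert_array_equal(a, b)

    def test_monte_carlo_mean_matches_curve(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        S = np.array([1.0, 0.85, 0.6, 0.45, 0.3])
        curve = SurvivalCurve(t, S)
        n0, nrep = 40, 10_000
        rng = np.random.default_rng(99)
        sums = np.zeros(t.size)
        for _ in range(nrep):
            sums += simulate_survivors(curve, n0, t, rng)
        mean = sums / nrep
        se = np.sqrt(n0 * S * (1 - S) / nrep)
        np.testing.assert_array_less(
            np.abs(mean[1:] - n0 * S[1:]), 3 * se[1:] + 1e-9
        )
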