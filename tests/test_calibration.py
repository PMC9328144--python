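import math

import numpy as np
import pytest

from gutsred import (
    FitOptions,
    ITParams,
    SDParams,
    SurvivalDataset,
    TestDesign,
    Treatment,
    constant_profile,
    fit,
    generate_test,
    goodness_of_fit,
    log_likelihood,
    profile_ci,
)
from gutsred.calibration import FitResult, default_bounds

FAST = FitOptions(n_screen=60, n_refine=4)


def _single_treatment(counts, times=(0.0, 1.0), conc=0.0):
    times = np.asarray(times, dtype=float)
    return SurvivalDataset(
        times,
        (Treatment(constant_profile(conc, times[-1]) if conc > 0 else
                   constant_profile(0.0, times[-1]), np.asarray(counts)),
         ),
    )


class TestLogLikelihood:
    def test_hand_computed_single_interval(self):
        # 10 fish, S(1) = 0.6 arranged through pure background hazard:
        # LL = 4 ln 0.4 + 6 ln 0.6
        data = _single_treatment([10, 6])
        params = SDParams(kD=1.0, zw=5.0, bw=0.0, hb=-math.log(0.6))
        expected = 4 * math.log(0.4) + 6 * math.log(0.6)
        assert log_likelihood(params, data, "SD") == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-6.7301, abs=1e-4)

    def test_perfect_survival_no_deaths_gives_zero(self):
        data = _single_treatment([10, 10])
        params = SDParams(kD=1.0, zw=5.0, bw=0.0, hb=0.0)  # S == 1
        assert log_likelihood(params, data, "SD") == 0.0

    def test_floor_guard_with_impossible_deaths(self):
        data = _single_treatment([10, 6])
        params = SDParams(kD=1.0, zw=5.0, bw=0.0, hb=0.0)  # S == 1, yet 4 died
        ll = log_likelihood(params, data, "SD")
        assert ll == pytest.approx(4 * math.log(1e-30), rel=1e-6)

    def test_increasing_counts_rejected(self):
        data = _single_treatment([10, 12])
        with pytest.raises(ValueError, match="increase"):
            log_likelihood(SDParams(1, 1, 1, 0), data, "SD")

    def test_it_variant_inferred_from_type(self):
        data = _single_treatment([10, 10])
        assert log_likelihood(ITParams(1, 5, 2, 0.0), data) == 0.0

    def test_treatment_order_invariance(self, sd_dataset, sd_truth):
        reversed_data = SurvivalDataset(
            sd_dataset.observation_times, tuple(reversed(sd_dataset.treatments))
        )
        assert log_likelihood(sd_truth, sd_dataset) == pytest.approx(
            log_likelihood(sd_truth, reversed_data), rel=1e-12
        )


class TestFit:
    def test_recovers_sd_parameters_within_ci(self, sd_dataset, sd_truth):
        res = fit(sd_dataset, "SD", options=FAST, seed=1)
        assert res.converged
        for name in ("kD", "zw", "bw"):
            lo, hi = res.ci[name]
            assert lo <= getattr(sd_truth, name) <= hi
            truth = getattr(sd_truth, name)
            assert abs(getattr(res.params, name) - truth) <= 0.35 * truth

    def test_recovers_it_parameters(self, it_dataset, it_truth):
        # single-replicate sanity check; the 100-replicate interval-coverage
        # statistics live in the acceptance suite
        res = fit(it_dataset, "IT", options=FAST, seed=1)
        assert res.converged
        lo, hi = res.ci["mw"]
        assert lo <= it_truth.mw <= hi
        for name in ("kD", "mw", "beta"):
            est, truth = getattr(res.params, name), getattr(it_truth, name)
            assert truth / 2 <= est <= truth * 2

    def test_best_fit_beats_truth(self, sd_dataset, sd_truth):
        res = fit(sd_dataset, "SD", options=FAST, seed=1)
        assert res.loglik >= log_likelihood(sd_truth, sd_dataset) - 1e-9

    def test_deterministic_under_seed(self, sd_dataset):
        opts = FitOptions(n_screen=40, n_refine=3, compute_ci=False)
        a = fit(sd_dataset, "SD", options=opts, seed=7)
        b = fit(sd_dataset, "SD", options=opts, seed=7)
        np.testing.assert_array_equal(a.param_values(), b.param_values())
        assert a.loglik == b.loglik

    def test_zero_deaths_pins_threshold_at_upper_bound(self):
        times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        treatments = tuple(
            Treatment(constant_profile(c, 4.0), np.full(5, 40))
            for c in (0.0, 2.0, 10.0)
        )
        data = SurvivalDataset(times, treatments)
        res = fit(data, "SD", options=FitOptions(n_screen=40, n_refine=3,
                                                 compute_ci=False), seed=0)
        hi = res.bounds["zw"][1]
        assert res.params.zw == pytest.approx(hi, rel=1e-6)
        assert res.boundary_flags["zw"]

    def test_requires_two_treatments(self):
        data = _single_treatment([10, 9])
        with pytest.raises(ValueError, match="2 treatments"):
            fit(data, "SD")


class TestProfileCI:
    def test_interval_contains_best_fit(self, sd_dataset):
        res = fit(sd_dataset, "SD", options=FitOptions(n_screen=40, n_refine=3,
                                                       compute_ci=False), seed=1)
        interval = profile_ci(res, sd_dataset, "kD")
        assert interval[0] <= res.params.kD <= interval[1]

    def test_no_partial_kill_leaves_killing_rate_unbounded(self):
        # all-or-nothing mortality between adjacent concentrations carries
        # no information on how fast deaths occur once above threshold
        times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        alive = np.full(5, 40)
        dead_fast = np.array([40, 0, 0, 0, 0])
        treatments = tuple(
            Treatment(constant_profile(c, 4.0), s)
            for c, s in [(0.0, alive), (1.0, alive), (2.0, alive),
                         (8.0, dead_fast), (16.0, dead_fast)]
        )
        data = SurvivalDataset(times, treatments)
        res = fit(data, "SD", options=FitOptions(n_screen=60, n_refine=4), seed=0)
        assert res.ci["bw"][1] == pytest.approx(res.bounds["bw"][1], rel=1e-6)
        assert res.boundary_flags["bw"]


class TestGoodnessOfFit:
    def _result_with(self, params, data, variant="SD"):
        return FitResult(
            variant=variant, params=params, loglik=0.0, ci={}, converged=True,
            n_starts=0, boundary_flags={}, bounds=default_bounds(data, variant),
        )

    def test_perfect_predictions_zero_metrics(self):
        data = _single_treatment([10, 10], conc=1.0)
        res = self._result_with(SDParams(1.0, 5.0, 0.0, 0.0), data)
        gof = goodness_of_fit(res, data)
        assert gof.nrmse == 0.0
        assert all(v == 0.0 for v in gof.sppe.values())

    def test_sppe_definition(self):
        # observed {10, 6}, predicted {10, 8} -> sppe = -20
        data = _single_treatment([10, 6], conc=1.0)
        res = self._result_with(SDParams(1.0, 5.0, 0.0, -math.log(0.8)), data)
        gof = goodness_of_fit(res, data)
        assert list(gof.sppe.values())[0] == pytest.approx(-20.0, abs=1e-9)

    def test_recovery_fit_inside_screening_bands(self, sd_dataset):
        res = fit(sd_dataset, "SD", options=FitOptions(n_screen=60, n_refine=4,
                                                       compute_ci=False), seed=1)
        gof = goodness_of_fit(res, sd_dataset)
        assert gof.nrmse < 0.5
        assert all(abs(v) < 50 for v in gof.sppe.values())
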