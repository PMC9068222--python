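"""Estimators: retention, error sensitivity, tied fits, rates, bootstrap, AIC."""

import numpy as np
import pandas as pd
import pytest

from adaptcomp import LearnerParams
from adaptcomp.core import simulate_competition
from adaptcomp.estimation import (
    Observation,
    aic,
    bootstrap,
    convert_retention,
    empirical_error_sensitivity,
    fit_exponential,
    fit_retention,
    fit_state_space,
    interference_metrics,
    linfit_ci,
    model_compare,
    savings_metrics,
)
from adaptcomp.synth import make_schedule


class TestRetention:
    def test_exact_geometric_sequence(self):
        assert fit_retention([9.0, 8.1, 7.29], 10.0) == pytest.approx(0.9, abs=1e-7)

    def test_constant_sequence_hits_unit_boundary(self):
        assert fit_retention([10.0, 10.0, 10.0], 10.0) == pytest.approx(1.0, abs=1e-6)

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(0)
        a, y_ss = 0.943, 20.0
        n = np.arange(1, 16)
        estimates = [
            fit_retention(a**n * y_ss + rng.normal(0, 0.5, 15), y_ss)
            for _ in range(500)
        ]
        assert abs(np.mean(estimates) - a) < 0.02

    def test_zero_asymptote_rejected(self):
        with pytest.raises(ValueError):
            fit_retention([1.0, 0.5], 0.0)

    def test_sign_mismatch_warns_but_fits(self):
        with pytest.warns(UserWarning):
            fit_retention([-9.0, -8.1], 10.0)

    @pytest.mark.parametrize(
        "a,k,direction,expected",
        [
            (0.943, 4, "per_step_root", 0.985),
            (0.77, 1, "per_step_root", 0.77),
            (0.77, 1, "compound", 0.77),
            (0.899, 4, "per_step_root", 0.9737),
            (0.985, 3, "compound", 0.985**3),
        ],
    )
    def test_convert_retention(self, a, k, direction, expected):
        assert convert_retention(a, k, direction) == pytest.approx(expected, abs=5e-4)

    def test_convert_retention_validates(self):
        with pytest.raises(ValueError):
            convert_retention(0.9, 0)
        with pytest.raises(ValueError):
            convert_retention(1.2, 4)


class TestEmpiricalErrorSensitivity:
    def test_difference_quotient_without_forgetting(self):
        visits = pd.DataFrame(
            {"target": 0, "trial": [1, 2], "y": [10.0, 12.0], "e": [10.0, 1.0]}
        )
        res = empirical_error_sensitivity(visits, retention=1.0, filter="none")
        assert res.table["b"].iloc[0] == pytest.approx(0.2)

    def test_decay_corrected_across_a_gap(self):
        visits = pd.DataFrame(
            {"target": "T", "trial": [1, 5], "y": [10.0, 12.0], "e": [8.0, 1.0]}
        )
        res = empirical_error_sensitivity(visits, retention=0.985, filter="none")
        assert res.table["b"].iloc[0] == pytest.approx((12 - 0.985**4 * 10) / 8)

    def test_zero_error_pairs_dropped_and_counted(self):
        visits = pd.DataFrame(
            {"target": 0, "trial": [1, 2, 3], "y": [10.0, 12.0, 13.0], "e": [0.0, 5.0, 1.0]}
        )
        res = empirical_error_sensitivity(visits, retention=1.0, filter="none")
        assert res.n_zero_error == 1
        assert len(res.table) == 1

    def test_inverts_noiseless_simulation_exactly(self):
        params = LearnerParams(a_i=0.943, b_i=0.35)
        sched = make_schedule(
            "abrupt", rotation=30, rotation_epochs=60, trials_per_epoch=1, n_targets=1
        )
        trace = simulate_competition(params, sched)
        rot = sched.feedback_mode == "rotated"
        trials = np.flatnonzero(rot) + 1
        visits = pd.DataFrame(
            {
                "target": 0,
                "trial": trials,
                "y": trace.x_i[rot],
                "e": trace.e_target[rot],
            }
        )
        res = empirical_error_sensitivity(visits, retention=0.943, filter="none")
        assert np.allclose(res.table["b"], 0.35, atol=1e-10)
        assert res.summary == pytest.approx(0.35, abs=1e-10)

    def test_mad_filter_flags_planted_outlier(self):
        rng = np.random.default_rng(0)
        b = 0.3 + rng.normal(0, 0.01, 40)
        b[17] = 5.0
        visits = pd.DataFrame(
            {
                "target": 0,
                "trial": np.arange(1, 42),
                "y": np.zeros(41),
                "e": np.ones(41),
            }
        )
        # craft y so that consecutive quotients equal b with retention 1
        visits["y"] = np.concatenate([[0.0], np.cumsum(b)])
        res = empirical_error_sensitivity(visits, retention=1.0, filter="mad")
        assert bool(res.table["outlier"].iloc[17])
        assert res.table["outlier"].sum() <= 3

    def test_single_visit_rejected(self):
        visits = pd.DataFrame({"target": 0, "trial": [1], "y": [1.0], "e": [1.0]})
        with pytest.raises(ValueError):
            empirical_error_sensitivity(visits, retention=1.0)


class TestStateSpaceFit:
    def test_noiseless_identifiability(self):
        sched = make_schedule(
            "abrupt", rotation=30, rotation_epochs=50, probe_epochs=3,
            trials_per_epoch=4, n_targets=4,
        )
        true = LearnerParams(a_i=0.97, b_i=0.12, a_e=0.92, b_e=0.2)
        trace = simulate_competition(true, sched)
        state = np.where(sched.probe == "exclusion", "implicit", "total")
        obs = Observation(
            sched, np.where(state == "implicit", trace.x_i, trace.y), state
        )
        fit = fit_state_space([obs], model="competition", n_starts=6, seed=0)
        assert fit.rss <= 1e-10
        for name, value in (("a_i", 0.97), ("b_i", 0.12), ("a_e", 0.92), ("b_e", 0.2)):
            assert fit.estimates[name] == pytest.approx(value, abs=1e-3)

    def test_two_exposure_sensitivity_increases_recovered(self):
        # savings modelled as sensitivity increases of 41.5% (implicit) and
        # 70.6% (explicit) between exposures, shared retention
        sched = make_schedule(
            "washout_savings", rotation=30, exposure_epochs=60, washout_epochs=70,
            trials_per_epoch=4, n_targets=4,
        )
        gen = LearnerParams(
            a_i=0.9829, b_i=0.0629, a_e=0.9278, b_e=0.0632,
            exposure_overrides=((0.0629, 0.0632), (0.0629 * 1.415, 0.0632 * 1.706)),
        )
        trace = simulate_competition(gen, sched)
        n = sched.n_trials
        dbi, dbe = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            obs_hi = Observation(sched, trace.y + rng.normal(0, 1.0, n), "total")
            obs_lo = Observation(sched, trace.x_i + rng.normal(0, 1.0, n), "implicit")
            fit = fit_state_space(
                [obs_hi, obs_lo],
                model="competition",
                tie_map={
                    "a_i": "shared", "a_e": "shared",
                    "b_i": "per_exposure", "b_e": "per_exposure",
                },
                n_starts=4,
                seed=0,
            )
            e = fit.estimates
            dbi.append(100 * (e["b_i[1]"] / e["b_i[0]"] - 1))
            dbe.append(100 * (e["b_e[1]"] / e["b_e[0]"] - 1))
        assert np.mean(dbi) == pytest.approx(41.5, abs=5.0)
        assert np.mean(dbe) == pytest.approx(70.6, abs=5.0)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_state_space([], model="competition")

    def test_unknown_tie_parameter_rejected(self):
        sched = make_schedule("abrupt", rotation=30, rotation_epochs=5)
        obs = Observation(sched, np.zeros(sched.n_trials), "total")
        with pytest.raises(ValueError, match="unknown parameters"):
            fit_state_space([obs], tie_map={"gamma": "shared"})

    def test_all_unobserved_rejected(self):
        sched = make_schedule("abrupt", rotation=30, rotation_epochs=5)
        obs = Observation(sched, np.full(sched.n_trials, np.nan), "total")
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_state_space([obs])

    def test_missing_implicit_observations_flagged(self):
        sched = make_schedule("abrupt", rotation=30, rotation_epochs=10)
        true = LearnerParams(a_i=0.97, b_i=0.12, a_e=0.92, b_e=0.2)
        trace = simulate_competition(true, sched)
        obs = Observation(sched, trace.y, "total")
        fit = fit_state_space([obs], model="competition", n_starts=2, seed=0)
        assert "no_implicit_observations" in fit.flags


class TestBootstrap:
    def test_degenerate_cohort_gives_zero_width_interval(self):
        res = bootstrap(np.full(20, 3.0), np.mean, n_boot=200, seed=0)
        assert res.ci_low == res.ci_high == 3.0

    def test_same_seed_same_interval(self):
        data = np.random.default_rng(1).normal(size=40)
        a = bootstrap(data, np.mean, n_boot=500, seed=7)
        b = bootstrap(data, np.mean, n_boot=500, seed=7)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_interval_coverage_near_nominal(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(200):
            data = rng.normal(size=50)
            res = bootstrap(data, np.mean, n_boot=500, seed=rep)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert 0.90 <= hits / 200 <= 0.99

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap(np.ones(5), np.mean, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap(np.array([]), np.mean, n_boot=10)


class TestExponentialFit:
    def test_recovers_generating_curve(self):
        n = np.arange(1, 61)
        fit = fit_exponential(30 * (1 - np.exp(-0.1 * n)), baseline=0.0)
        assert fit.rate == pytest.approx(0.1, abs=1e-4)
        assert fit.asymptote == pytest.approx(30.0, abs=1e-2)
        assert fit.x_intercept is None  # starts at zero, never crosses

    def test_flat_curve_has_zero_rate(self):
        fit = fit_exponential([5.0, 5.0, 5.0, 5.0], baseline=5.0)
        assert fit.rate == 0.0

    def test_x_intercept_solved_from_the_fit(self):
        n = np.arange(1, 61)
        fit = fit_exponential(30 - 40 * np.exp(-0.1 * n), baseline=-10.0)
        assert fit.x_intercept == pytest.approx(np.log(4 / 3) / 0.1, abs=1e-3)

    def test_nonfinite_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, np.nan, 2.0], baseline=0.0)


class TestSavingsAndInterference:
    @staticmethod
    def _curve(rate, n=60, asy=30.0, start=0.0):
        k = np.arange(1, n + 1)
        return asy + (start - asy) * np.exp(-rate * k)

    def test_identical_exposures_are_null(self):
        pre = np.zeros(5)
        curve = np.concatenate([pre, self._curve(0.1)])
        m = savings_metrics(curve, curve.copy(), 0.0, 0.0, early_window=5)
        assert m.rate_ratio == pytest.approx(1.0, abs=1e-6)
        assert m.angle_contrast == pytest.approx(0.0, abs=1e-9)

    def test_doubled_rate_doubles_the_ratio(self):
        pre = np.zeros(5)
        c1 = np.concatenate([pre, self._curve(0.1)])
        c2 = np.concatenate([pre, self._curve(0.2)])
        m = savings_metrics(c1, c2, 0.0, 0.0, early_window=5)
        assert m.rate_ratio == pytest.approx(2.0, abs=1e-3)
        assert m.angle_contrast > 0

    def test_window_beyond_curve_rejected(self):
        with pytest.raises(ValueError):
            savings_metrics(np.zeros(6), np.zeros(6), 0.0, 0.0, early_window=5)

    def test_mirror_symmetric_exposures_ratio_one(self):
        a = self._curve(0.12, start=0.0)
        m = interference_metrics(np.concatenate([[0.0], a]), -np.concatenate([[0.0], a]))
        assert m["rate_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_slower_b_period_flags_interference(self):
        a = np.concatenate([[0.0], self._curve(0.12)])
        b = -np.concatenate([[0.0], self._curve(0.05)])
        m = interference_metrics(a, b)
        assert m["rate_ratio"] < 1.0

    def test_post_crossing_refit_and_its_failure_mode(self):
        # B starts from the opposite adapted state and crosses zero
        k = np.arange(0, 80)
        b_latent = 30 - 60 * np.exp(-0.08 * k)  # starts at -30, crosses up
        m = interference_metrics(
            np.concatenate([[0.0], self._curve(0.08, n=79)]),
            -b_latent,
            mode="post_zero_crossing",
        )
        assert m["rate_B"] == pytest.approx(0.08, abs=0.01)
        with pytest.raises(ValueError, match="crosses"):
            interference_metrics(
                np.concatenate([[0.0], self._curve(0.08, n=79)]),
                -self._curve(0.08, n=80),
                mode="post_zero_crossing",
            )


class TestModelComparison:
    def test_aic_arithmetic(self):
        assert aic(10.0, 100, 2) == pytest.approx(100 * np.log(0.1) + 4, abs=1e-6)

    def test_fewer_parameters_win_ties(self):
        table = model_compare({"two": [aic(5.0, 50, 2)], "three": [aic(5.0, 50, 3)]})
        assert table["winner"].iloc[0] == "two"

    def test_zero_rss_rejected(self):
        with pytest.raises(ValueError):
            aic(0.0, 10, 1)

    def test_winner_counts_tally(self):
        table = model_compare({"a": [1.0, 5.0, 2.0], "b": [2.0, 1.0, 3.0]})
        assert table.attrs["winner_counts"] == {"a": 2, "b": 1}


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linfit_ci(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_ci[1] - fit.slope_ci[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.rho == pytest.approx(1.0)

    def test_confidence_interval_coverage(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            x = np.linspace(0, 30, 9)
            y = -0.86 * x + 25.8 + rng.normal(0, 1, 9)
            fit = linfit_ci(x, y)
            hits += fit.slope_ci[0] <= -0.86 <= fit.slope_ci[1]
        assert hits / 200 >= 0.88  # nominal 95% less Monte-Carlo slack

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linfit_ci(np.ones(5), np.arange(5.0))
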