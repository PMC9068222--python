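"""Simulators and closed-form steady states of the learner architectures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptcomp import (
    LearnerParams,
    PerturbationSchedule,
    UnstableParameterError,
    coupled_steady_state,
    dual_error_steady_state,
    error_clamp_steady_state,
    implicit_from_total,
    implicit_gain,
    simulate_competition,
    simulate_dual_error,
    simulate_independence,
    steady_state_competition,
    steady_state_independence,
)


def constant_schedule(r, n, **kw):
    return PerturbationSchedule.constant(r, n, **kw)


class TestSimulators:
    def test_zero_rotation_stays_at_zero(self):
        sched = constant_schedule(0.0, 100)
        params = LearnerParams(a_i=0.98, b_i=0.2, a_e=0.9, b_e=0.3)
        for sim in (simulate_competition, simulate_independence):
            trace = sim(params, sched)
            assert np.all(trace.x_i == 0) and np.all(trace.x_e == 0)
            assert np.all(trace.y == 0)

    def test_competition_converges_to_coupled_steady_state(self, haith_params):
        sched = constant_schedule(30.0, 3000)
        trace = simulate_competition(haith_params, sched)
        ss = coupled_steady_state(haith_params, 30.0)
        assert abs(trace.x_i[-1] - ss.x_i_ss) <= 1e-6
        assert abs(trace.x_e[-1] - ss.x_e_ss) <= 1e-6
        assert ss.x_i_ss == pytest.approx(19.87, abs=0.005)
        assert ss.x_e_ss == pytest.approx(4.73, abs=0.005)

    def test_no_forgetting_drives_error_to_zero(self):
        params = LearnerParams(a_i=1.0, b_i=0.1, a_e=1.0, b_e=0.1)
        trace = simulate_competition(params, constant_schedule(30.0, 2000))
        assert trace.x_i[-1] + trace.x_e[-1] == pytest.approx(30.0, abs=1e-9)
        assert trace.e_target[-1] == pytest.approx(0.0, abs=1e-9)

    def test_trace_bookkeeping_invariants(self, haith_params):
        n = 50
        probe = np.array(["none"] * n, dtype=object)
        probe[20:24] = "exclusion"
        fb = np.array(["rotated"] * n, dtype=object)
        fb[20:24] = "none"
        sched = PerturbationSchedule(
            rotation=np.full(n, 30.0), probe=probe, feedback_mode=fb
        )
        trace = simulate_competition(haith_params, sched)
        assert np.allclose(trace.y, trace.x_i + trace.x_e)
        on = sched.probe == "none"
        assert np.allclose(
            trace.e_target[on], 30.0 - trace.x_i[on] - trace.x_e[on]
        )
        assert np.allclose(trace.e_spe[on], 30.0 - trace.x_i[on])
        assert np.all(np.isnan(trace.e_target[~on]))
        # probe trials retain without learning
        assert trace.x_i[21] == pytest.approx(haith_params.a_i * trace.x_i[20])

    def test_independence_ignores_prescribed_strategy(self):
        params = LearnerParams(a_i=0.9, b_i=0.2)
        sched = constant_schedule(30.0, 400)
        t_aim = simulate_independence(
            params, sched, explicit_mode="prescribed", aim=np.full(400, 10.0)
        )
        t_zero = simulate_independence(
            params, sched, explicit_mode="prescribed", aim=np.zeros(400)
        )
        assert np.array_equal(t_aim.x_i, t_zero.x_i)  # bitwise identical
        assert t_aim.x_i[-1] == pytest.approx(20.0, abs=1e-9)

    def test_clamped_feedback_integrates_fixed_error(self):
        n = 3000
        sched = PerturbationSchedule(
            rotation=np.zeros(n),
            feedback_mode=np.array(["clamped"] * n, dtype=object),
            clamp_error=np.full(n, 5.0),
        )
        trace = simulate_independence(LearnerParams(a_i=0.98, b_i=0.3), sched)
        assert trace.x_i[-1] == pytest.approx(75.0, abs=1e-3)

    def test_aim_length_mismatch_raises(self):
        sched = constant_schedule(30.0, 10)
        with pytest.raises(ValueError, match="aim sequence"):
            simulate_competition(
                LearnerParams(a_i=0.9, b_i=0.1),
                sched,
                explicit_mode="prescribed",
                aim=np.zeros(5),
            )


class TestDualError:
    def test_reduces_to_competition_when_landmark_absent(self):
        params = LearnerParams(a_i=0.95, b_i=0.1)
        sched = constant_schedule(45.0, 300)  # dual_target_active defaults False
        aim = np.zeros(300)
        dual = simulate_dual_error(params, sched, aim)
        comp = simulate_competition(params, sched, explicit_mode="prescribed", aim=aim)
        assert np.allclose(dual.x_i, comp.x_i)
        assert np.allclose(dual.x_i1 + dual.x_i2, dual.x_i)
        assert dual.x_i[-1] == pytest.approx(30.0, abs=1e-6)  # b r / (1 - a + b)

    def test_aiming_landmark_halves_learning(self):
        params = LearnerParams(a_i=0.95, b_i=0.1)
        n = 2000
        sched = PerturbationSchedule(
            rotation=np.full(n, 45.0),
            dual_target_active=np.ones(n, dtype=bool),
        )
        aim = np.full(n, 45.0)
        aim[:2] = 0.0  # strategy instructed shortly after onset
        dual = simulate_dual_error(params, sched, aim)
        assert dual.x_i[-1] == pytest.approx(18.0, abs=1e-6)
        assert dual.x_i[-1] == pytest.approx(
            dual_error_steady_state(0.95, 0.1, 45.0, 45.0), abs=1e-9
        )

    def test_missing_aim_sequence_raises(self):
        with pytest.raises(ValueError):
            simulate_dual_error(
                LearnerParams(a_i=0.95, b_i=0.1), constant_schedule(45.0, 10), aim=None
            )


class TestSteadyStates:
    def test_competition_reproduces_printed_relation(self):
        # x_i = 0.86 (30 - x_e) at the limit-PT estimates
        assert steady_state_competition(0.943, 0.35, 30.0, 10.0) == pytest.approx(
            17.20, abs=0.005
        )
        assert steady_state_competition(0.9, 0.4, 30.0, 30.0) == 0.0
        assert steady_state_competition(0.9, 0.0, 30.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "a,b,r,expected",
        [(0.9, 0.2, 30.0, 20.0), (0.7, 0.3, 0.0, 0.0), (1.0, 0.5, 10.0, 10.0)],
    )
    def test_independence_closed_form(self, a, b, r, expected):
        assert steady_state_independence(a, b, r) == pytest.approx(expected)

    def test_coupled_steady_state_values(self, haith_params):
        ss = coupled_steady_state(haith_params, 30.0)
        assert ss.x_i_ss == pytest.approx(19.8698, abs=1e-3)
        assert ss.x_e_ss == pytest.approx(4.7284, abs=1e-3)
        assert ss.x_T_ss == ss.x_i_ss + ss.x_e_ss
        zero = coupled_steady_state(haith_params, 0.0)
        assert zero.x_i_ss == zero.x_e_ss == zero.x_T_ss == 0.0

    def test_exposure_two_increase_below_five_percent(self, haith_params):
        day2 = LearnerParams(a_i=0.9829, b_i=0.089, a_e=0.9278, b_e=0.1078)
        x1 = coupled_steady_state(haith_params, 30.0).x_i_ss
        x2 = coupled_steady_state(day2, 30.0).x_i_ss
        assert x2 == pytest.approx(20.28, abs=0.01)
        change = 100.0 * (x2 / x1 - 1.0)
        assert 0 < change < 5.0
        assert change == pytest.approx(2.1, abs=0.05)

    def test_degenerate_integrator_pair_has_no_unique_steady_state(self):
        params = LearnerParams(a_i=1.0, b_i=0.5, a_e=1.0, b_e=0.9)
        with pytest.raises(UnstableParameterError):
            coupled_steady_state(params, 30.0)

    def test_implicit_gain_values(self):
        assert round(implicit_gain(0.943, 0.35), 2) == 0.86
        assert implicit_gain(1.0, 0.4) == 1.0
        assert implicit_gain(0.899, 0.193) == pytest.approx(0.656, abs=5e-4)

    def test_implicit_from_total(self):
        assert implicit_from_total(0.6, 30.0, 30.0) == 0.0
        assert implicit_from_total(0.5, 30.0, 20.0) == pytest.approx(10.0)
        # substitution identity with the explicit form via x_T = x_i + x_e
        p = implicit_gain(0.943, 0.35)
        x_i = steady_state_competition(0.943, 0.35, 30.0, 10.0)
        assert implicit_from_total(p, 30.0, x_i + 10.0) == pytest.approx(x_i, abs=1e-9)
        with pytest.raises(ValueError):
            implicit_from_total(1.0, 30.0, 10.0)

    def test_error_clamp_steady_state(self):
        assert error_clamp_steady_state(0.98, 0.3, 1.0) == pytest.approx(15.0)
        assert error_clamp_steady_state(0.98, 0.3, 5.0) == pytest.approx(75.0)
        assert error_clamp_steady_state(0.9, 0.0, 7.0) == 0.0
        with pytest.raises(UnstableParameterError):
            error_clamp_steady_state(1.0, 0.3, 5.0)

    @pytest.mark.parametrize(
        "a,b,r,aim,expected",
        [
            (0.95, 0.1, 45.0, 45.0, 18.0),
            (0.9, 0.2, 20.0, 40.0, 0.0),  # aim = 2r cancels the two errors
            (0.95, 0.1, 45.0, 0.0, 36.0),
        ],
    )
    def test_dual_error_closed_form(self, a, b, r, aim, expected):
        assert dual_error_steady_state(a, b, r, aim) == pytest.approx(expected)


class TestProperties:
    @given(
        a_i=st.floats(0.6, 0.995),
        b_i=st.floats(0.02, 0.5),
        a_e=st.floats(0.6, 0.995),
        b_e=st.floats(0.02, 0.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_simulation_matches_closed_form(self, a_i, b_i, a_e, b_e):
        try:
            params = LearnerParams(a_i=a_i, b_i=b_i, a_e=a_e, b_e=b_e)
        except UnstableParameterError:
            return
        lam = max(
            abs(np.linalg.eigvals([[a_i - b_i, -b_i], [-b_e, a_e - b_e]]))
        )
        if lam >= 0.999:
            return
        n = min(int(np.log(1e-9 / 90.0) / np.log(lam)) + 2, 30000)
        trace = simulate_competition(params, constant_schedule(30.0, n))
        ss = coupled_steady_state(params, 30.0)
        assert abs(trace.x_i[-1] - ss.x_i_ss) <= 1e-6
        assert abs(trace.x_e[-1] - ss.x_e_ss) <= 1e-6

    @given(x_e=st.floats(-20.0, 50.0), delta=st.floats(0.5, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_competition_strictly_decreasing_in_strategy(self, x_e, delta):
        lo = steady_state_competition(0.943, 0.35, 30.0, x_e + delta)
        hi = steady_state_competition(0.943, 0.35, 30.0, x_e)
        assert lo < hi

    def test_gain_insensitive_to_sensitivity_changes(self):
        # doubling b_i changes p_i by far less than 2x near full retention
        p0 = implicit_gain(0.9829, 0.0629)
        p1 = implicit_gain(0.9829, 2 * 0.0629)
        rel_p = p1 / p0 - 1.0
        assert 0 < rel_p < 1.0  # relative change in gain << relative change in b
        # analytic sensitivity |dp/db| = (1-a)/(1-a+b)^2
        a, b = 0.9829, 0.0629
        num = (implicit_gain(a, b + 1e-6) - implicit_gain(a, b)) / 1e-6
        assert num == pytest.approx((1 - a) / (1 - a + b) ** 2, rel=1e-3)
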