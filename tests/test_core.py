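"""Elementary equations: costs, logits, averages, meeting functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medmarket import (
    DegenerateSplitError,
    InvalidInputError,
    ModelParams,
    ModeSplit,
    doctor_futility,
    doctor_logsums_and_probs,
    mode1_averages,
    patient_costs,
    patient_mode_split,
    patient_wait_mode1,
    patient_wait_mode2,
)

PARAMS = ModelParams()


class TestPatientCosts:
    def test_costs_coincide_when_waits_vanish(self):
        c1, c2 = patient_costs(15.0, 0.25, 0.0, 0.0, PARAMS)
        assert c1 == c2 == 15.0 + 10.0 * 0.25

    def test_example_pair_cost(self):
        # pair (1,2): t = 0.25 h, F = 60*0.25, patient wait half an hour
        c1, _ = patient_costs(15.0, 0.25, 0.5, 0.0, PARAMS)
        assert c1 == pytest.approx(27.5)

    def test_symmetry_when_waits_equal_and_no_departure_delay(self):
        c1, c2 = patient_costs(12.0, 0.4, 0.3, 0.3, PARAMS)
        assert c1 == pytest.approx(c2)

    def test_departure_delay_raises_app_cost_only(self):
        p = PARAMS.replace(z_bar=0.1)
        c1, c2 = patient_costs(12.0, 0.4, 0.3, 0.3, p)
        assert c2 - c1 == pytest.approx(p.mu1 * 0.1)

    def test_negative_wait_rejected(self):
        with pytest.raises(InvalidInputError):
            patient_costs(10.0, 0.2, -0.1, 0.0, PARAMS)


class TestPatientModeSplit:
    def test_equal_costs_split_evenly(self):
        s = patient_mode_split(np.array([30.0]), np.array([30.0]), np.array([10.0]), 0.2)
        assert s.q1[0] == pytest.approx(5.0)

    def test_zero_dispersion_ignores_costs(self):
        s = patient_mode_split(np.array([100.0]), np.array([1.0]), np.array([10.0]), 0.0)
        assert s.q1[0] == pytest.approx(5.0)

    def test_logit_share_value(self):
        s = patient_mode_split(np.array([27.5]), np.array([20.0]), np.array([10.0]), 0.2)
        assert s.q1[0] == pytest.approx(10.0 / (1.0 + np.exp(1.5)), rel=1e-12)

    def test_infinite_cost_sends_demand_to_other_mode(self):
        s = patient_mode_split(np.array([np.inf]), np.array([20.0]), np.array([10.0]), 0.2)
        assert s.q1[0] == 0.0 and s.q2[0] == 10.0

    @settings(deadline=None, derandomize=True)
    @given(
        c1=st.lists(st.floats(-500, 500), min_size=1, max_size=8),
        c2=st.data(),
        omega=st.floats(0, 5),
    )
    def test_conservation_is_exact(self, c1, c2, omega):
        n = len(c1)
        c2v = np.array(c2.draw(st.lists(st.floats(-500, 500), min_size=n, max_size=n)))
        demand = np.linspace(1.0, 9.0, n)
        s = patient_mode_split(np.array(c1), c2v, demand, omega)
        np.testing.assert_array_equal(s.q1 + s.q2, demand)
        assert (s.q1 >= 0).all() and (s.q2 >= 0).all()

    def test_departure_delay_monotonically_discourages_app_mode(self):
        shares = []
        for z in (0.0, 0.5, 1.0):
            p = PARAMS.replace(z_bar=z)
            c1, c2 = patient_costs(10.0, 0.2, 0.3, 0.1, p)
            s = patient_mode_split(np.atleast_1d(c1), np.atleast_1d(c2), np.array([10.0]), p.omega1)
            shares.append(s.q2[0])
        assert shares[0] > shares[1] > shares[2]

    def test_large_dispersion_concentrates_on_cheaper_mode(self):
        s = patient_mode_split(np.array([21.0]), np.array([20.0]), np.array([10.0]), 50.0)
        assert s.q2[0] / 10.0 > 1 - 1e-9


class TestMode1Averages:
    def test_uniform_demand_gives_arithmetic_mean(self, example_net):
        m = example_net.n_pairs
        split = ModeSplit(q1=np.full(m, 2.0), q2=example_net.demand - 0.0)
        f_bar, t_bar, _ = mode1_averages(split, example_net, PARAMS)
        assert f_bar == pytest.approx(example_net.fee.mean())
        assert t_bar == pytest.approx(example_net.service_time.mean())

    def test_point_mass_returns_that_pairs_fee(self, example_net):
        q1 = np.zeros(example_net.n_pairs)
        q1[3] = 4.0
        split = ModeSplit(q1=q1, q2=example_net.demand)
        f_bar, t_bar, _ = mode1_averages(split, example_net, PARAMS)
        assert f_bar == pytest.approx(example_net.fee[3])

    def test_proportional_split_reproduces_global_mean(self, example_net, initial_split):
        # with q1 = 0.7 P the weights are proportional to demand
        _, t_bar, _ = mode1_averages(initial_split, example_net, PARAMS)
        assert t_bar == pytest.approx(18.55 / 62.0)

    def test_empty_mode_raises(self, example_net):
        split = ModeSplit(q1=np.zeros(example_net.n_pairs), q2=example_net.demand)
        with pytest.raises(DegenerateSplitError):
            mode1_averages(split, example_net, PARAMS)


class TestDoctorFutility:
    def test_base_variant_value(self):
        u = doctor_futility(15.0, 0.25, 0.2, PARAMS, attractiveness=0.0)
        assert u == pytest.approx(-15.0 + 10.0 * 0.45)

    def test_profit_variant_reduces_to_base_at_unit_lambda(self):
        base = doctor_futility(15.0, 0.25, 0.2, PARAMS)
        profit = doctor_futility(15.0, 0.25, 0.2, PARAMS.replace(futility_variant="profit", lam=1.0))
        assert base == pytest.approx(profit)

    @pytest.mark.parametrize("variant", ["base", "profit"])
    def test_linearity_in_waiting_time(self, variant):
        p = PARAMS.replace(futility_variant=variant)
        u0 = doctor_futility(15.0, 0.25, 0.2, p)
        u1 = doctor_futility(15.0, 0.25, 0.2 + 0.3, p)
        assert u1 - u0 == pytest.approx(p.pi_t * 0.3)


class TestDoctorChoice:
    def test_identical_futilities_give_uniform_pair_choice(self):
        ch = doctor_logsums_and_probs(-3.0, np.full(5, -7.0), PARAMS, n_pairs=5)
        np.testing.assert_allclose(ch.p6, 0.2)

    def test_equal_logsums_split_modes_evenly(self):
        # one pair per mode with equal futility makes the logsums equal
        ch = doctor_logsums_and_probs(np.array([-4.0]), np.array([-4.0]), PARAMS)
        assert ch.l_id1 == pytest.approx(ch.l_id2)
        assert ch.p3 == pytest.approx(0.5)

    def test_two_pair_app_choice_value(self):
        ch = doctor_logsums_and_probs(-1.0, np.array([-10.5, -9.5]), PARAMS, n_pairs=2)
        expected = 1.0 / (1.0 + np.exp(-0.5))
        assert ch.p6[0] == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        u1=st.floats(-200, 200),
        u2=st.lists(st.floats(-200, 200), min_size=1, max_size=10),
    )
    def test_normalisation_for_arbitrary_finite_futilities(self, u1, u2):
        ch = doctor_logsums_and_probs(u1, np.array(u2), PARAMS, n_pairs=4)
        assert ch.p3 + ch.p4 == pytest.approx(1.0)
        assert ch.p5.sum() == pytest.approx(1.0)
        assert ch.p6.sum() == pytest.approx(1.0)


class TestMeetingFunctions:
    def test_unit_elasticity_closed_form(self):
        assert patient_wait_mode1(10.0, 4.0, PARAMS, efficiency=1.0) == pytest.approx(0.25)

    @settings(deadline=None, derandomize=True)
    @given(
        q=st.floats(0.1, 100),
        idle=st.floats(0.01, 100),
        a=st.floats(0.1, 10),
    )
    def test_general_form_matches_closed_form_at_unit_elasticities(self, q, idle, a):
        general = patient_wait_mode1(q, idle, PARAMS, efficiency=a)
        assert general == pytest.approx(1.0 / (a * idle), rel=1e-12)

    def test_fractional_elasticity_value(self):
        p = PARAMS.replace(alpha1=0.5, alpha2=1.0)
        assert patient_wait_mode1(4.0, 2.0, p, efficiency=1.0) == pytest.approx(1.0)

    def test_zero_idle_hours_signal_infinite_wait(self):
        assert np.isinf(patient_wait_mode1(5.0, 0.0, PARAMS))

    def test_app_mode_friction_constant(self):
        assert patient_wait_mode2(10.0, 1.0, PARAMS) == pytest.approx(1e-4)

    def test_wait_vanishes_as_friction_constant_grows(self):
        waits = [patient_wait_mode2(10.0, 1.0, PARAMS.replace(a_tilde=a)) for a in (1e2, 1e4, 1e6)]
        assert waits[0] > waits[1] > waits[2]

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            patient_wait_mode1(-1.0, 1.0, PARAMS)
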