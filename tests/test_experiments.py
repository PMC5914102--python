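"""Sweeps, per-pair report, crossing finder and display scenarios."""

import numpy as np
import pytest

from medmarket import (
    ModelParams,
    ScenarioSpec,
    default_scenarios,
    find_crossing,
    nearest_approach,
    per_pair_report,
    run_scenarios,
    solve_equilibrium,
    sweep_doctor_count,
    sweep_parameter,
)

PARAMS = ModelParams()


def nondegenerate(sweep, column):
    rec = sweep.records
    mask = ~rec["mode1_degenerate"].astype(bool)
    return rec.loc[mask, column].to_numpy(dtype=float)


class TestDoctorCountSweep:
    def test_single_point_grid_equals_direct_solve(self, example_net):
        sweep = sweep_doctor_count(example_net, PARAMS, grid=(100,))
        direct = solve_equilibrium(example_net, PARAMS)
        assert sweep.records.loc[100.0, "doctor_wait_mode1"] == pytest.approx(direct.doctor_wait_mode1)
        assert sweep.records.loc[100.0, "utilization_avg"] == pytest.approx(0.1855)

    def test_all_points_converged_and_flagged(self, doctor_sweep):
        assert doctor_sweep.all_converged
        assert list(doctor_sweep.records.index) == [20.0, 50.0, 80.0, 100.0, 150.0]

    def test_doctor_waits_rise_with_supply(self, doctor_sweep):
        w1 = nondegenerate(doctor_sweep, "doctor_wait_mode1")
        w2 = doctor_sweep.series("doctor_wait_mode2_mean")
        assert (np.diff(w1) >= -1e-9).all()
        assert (np.diff(w2) >= -1e-9).all()

    def test_patient_hospital_wait_falls_with_supply(self, doctor_sweep):
        wp1 = nondegenerate(doctor_sweep, "patient_wait_mode1")
        assert (np.diff(wp1) <= 1e-9).all()

    def test_utilizations_fall_with_supply(self, doctor_sweep):
        u1 = nondegenerate(doctor_sweep, "utilization_mode1")
        u2 = doctor_sweep.series("utilization_mode2")
        assert (np.diff(u1) <= 1e-9).all()
        assert (np.diff(u2) <= 1e-9).all()

    def test_app_patient_wait_negligible_throughout(self, doctor_sweep):
        assert (doctor_sweep.series("patient_wait_mode2") < 1e-3).all()

    def test_infeasible_entry_reported_but_sweep_continues(self, example_net):
        sweep = sweep_doctor_count(example_net, PARAMS, grid=(10, 100))
        assert not bool(sweep.records.loc[10.0, "converged"])
        assert "insufficient" in sweep.records.loc[10.0, "error"]
        assert bool(sweep.records.loc[100.0, "converged"])

    def test_grid_permutation_only_permutes_records(self, example_net):
        a = sweep_doctor_count(example_net, PARAMS, grid=(100, 50)).records.sort_index()
        b = sweep_doctor_count(example_net, PARAMS, grid=(50, 100)).records.sort_index()
        assert np.allclose(
            a["doctor_wait_mode1"].to_numpy(), b["doctor_wait_mode1"].to_numpy()
        )


class TestParameterSweeps:
    def test_unit_lambda_reproduces_base_futility_solution(self, example_net, lambda_sweep):
        base = solve_equilibrium(example_net, PARAMS)
        row = lambda_sweep.records.loc[1.0]
        assert row["doctor_wait_mode1"] == pytest.approx(base.doctor_wait_mode1, rel=1e-6)
        assert row["doctor_wait_mode2_mean"] == pytest.approx(base.doctor_wait_mode2_mean, rel=1e-6)

    def test_hospital_doctor_wait_nondecreasing_in_lambda(self, lambda_sweep):
        w1 = lambda_sweep.series("doctor_wait_mode1")
        assert (np.diff(w1) >= -1e-9).all()

    def test_hospital_doctor_wait_nondecreasing_in_omega4(self, omega4_sweep):
        w1 = omega4_sweep.series("doctor_wait_mode1")
        assert (np.diff(w1) >= -1e-9).all()

    def test_app_doctor_wait_falls_as_choices_sharpen(self, omega4_sweep):
        w2 = omega4_sweep.series("doctor_wait_mode2_mean")
        assert (np.diff(w2) <= 1e-9).all()

    def test_unknown_parameter_rejected(self, example_net):
        with pytest.raises(ValueError):
            sweep_parameter(example_net, PARAMS, "mu1", (1, 2))


class TestPerPairReport:
    def test_longest_consultations_carry_longest_app_waits(self, example_net):
        table = per_pair_report(example_net, PARAMS, n_doctors=100.0)
        app = table[table["group"] != "non-app"]
        top2 = set(app.nlargest(2, "doctor_wait")["group"])
        assert top2 == {"2-4", "4-2"}

    def test_symmetric_network_gives_equal_waits(self, symmetric_two_pair_net):
        table = per_pair_report(symmetric_two_pair_net, PARAMS, n_doctors=15.0)
        app = table[table["group"] != "non-app"]["doctor_wait"].to_numpy()
        assert app[0] == pytest.approx(app[1], rel=1e-9)

    def test_futility_gaps_match_log_demand_ratios(self, example_net):
        """At the solution the app-mode futility differences across pairs
        equal -(1/omega4) * log of the demand ratios."""
        res = solve_equilibrium(example_net, PARAMS.replace(n_doctors=100.0))
        from medmarket.model import _wait_free_futilities

        b1, _ = _wait_free_futilities(res.split, res.network, res.params)
        u2 = b1 + res.params.pi_t * res.allocation.w_id2
        q2 = res.split.q2
        expected = -np.log(q2 / q2[0]) / res.params.omega4
        np.testing.assert_allclose(u2 - u2[0], expected, atol=1e-8)


class TestFindCrossing:
    def test_analytic_intersection(self):
        assert find_crossing([0.0, 1.0], [0.0, 1.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_touching_grid_point_returned(self):
        assert find_crossing([1, 2, 3], [5, 4, 2], [6, 4, 1]) == 2

    def test_no_sign_change_signals_no_crossing(self):
        assert find_crossing([1, 2, 3], [5, 4, 3], [1, 1, 1]) is None

    def test_nearest_approach_picks_minimum_gap(self):
        assert nearest_approach([1, 2, 3], [5, 4, 3], [1, 2.9, 1]) == 2


@pytest.fixture(scope="module")
def table(example_net):
    return run_scenarios(example_net, PARAMS)


class TestScenarios:

    def test_traditional_market_serves_everyone_in_hospital(self, table):
        assert table.loc["traditional", "mode1_share"] == pytest.approx(1.0)

    def test_identical_specs_give_identical_rows(self, example_net):
        specs = [ScenarioSpec("a", {"n_doctors": 80.0}), ScenarioSpec("b", {"n_doctors": 80.0})]
        t = run_scenarios(example_net, PARAMS, specs)
        assert t.loc["a", "avg_doctor_wait"] == t.loc["b", "avg_doctor_wait"]
        assert t.loc["a", "avg_patient_wait"] == t.loc["b", "avg_patient_wait"]

    def test_displaying_doctor_information_does_not_shorten_waits(self, table):
        assert (
            table.loc["display_both", "avg_doctor_wait"]
            >= table.loc["display_patient", "avg_doctor_wait"] - 1e-9
        )
        assert (
            table.loc["display_both", "avg_patient_wait"]
            >= table.loc["display_patient", "avg_patient_wait"] - 1e-9
        )

    def test_all_scenarios_converge(self, table):
        assert table["converged"].all()
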