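"""Metrics and statistics: tracking error, improvement, ANOVA/Tukey, paired t."""

import numpy as np
import pytest

from tailopt.analysis import (
    compare_paired,
    compare_uniform_configs,
    improvement_percent,
    joint_effort_integrals,
    significance_symbol,
    tracking_error,
)
from tailopt.collocation import SolveResult


def _result(times, states, controls, cost=0.0):
    return SolveResult(
        times=np.asarray(times), states=np.asarray(states, dtype=float),
        controls=np.asarray(controls, dtype=float), cost=cost,
        solver_status="optimal", init_label="test", iterations=0,
        constraint_violation=0.0,
    )


class TestTrackingError:
    def test_zero_when_realized_equals_target(self, zero_traj):
        times = np.linspace(0.0, 0.5, 11)
        states = np.zeros((11, 10))
        r = _result(times, states, np.zeros((11, 2)))
        assert tracking_error(r, zero_traj) == 0.0

    def test_constant_offset_closed_form(self, zero_traj):
        """A constant offset d on one axis over T seconds integrates to d^2 T."""
        times = np.linspace(0.0, 0.5, 26)
        states = np.zeros((26, 10))
        states[:, 1] = 0.3
        r = _result(times, states, np.zeros((26, 2)))
        assert tracking_error(r, zero_traj) == pytest.approx(0.3**2 * 0.5,
                                                             rel=1e-12)

    def test_matches_solver_cost_on_solved_trial(self, model_1v, zero_traj):
        from tailopt.collocation import CollocationProblem, TimeGrid

        prob = CollocationProblem(model_1v, zero_traj,
                                  grid=TimeGrid(dt=0.1))
        res = prob.solve(prob.initial_guesses(0)[0][1], method="trust-constr",
                         maxiter=30)
        assert tracking_error(res, zero_traj, problem=prob) == pytest.approx(
            res.cost, abs=1e-8
        )


class TestImprovementPercent:
    @pytest.mark.parametrize("ref,new,expected", [
        (1.0, 0.5, 50.0), (2.0, 2.0, 0.0), (4.0, 1.0, 75.0),
    ])
    def test_formula(self, ref, new, expected):
        assert improvement_percent(ref, new) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement_percent(0.0, 1.0)


class TestEffortIntegrals:
    def test_constant_torques_closed_form(self):
        times = np.linspace(0.0, 0.5, 6)
        controls = np.tile([1.0, 2.0, 0.5, -1.0], (6, 1))  # 2 joints x 2 DOF
        r = _result(times, np.zeros((6, 14)), controls)
        eff = joint_effort_integrals(r)
        # joint 1: (1^2 + 2^2) * 0.5; joint 2: (0.25 + 1) * 0.5
        assert eff == pytest.approx([2.5, 0.625])

    def test_total_effort_bounded_by_cap_times_horizon(self):
        rng = np.random.default_rng(0)
        times = np.linspace(0.0, 0.5, 26)
        controls = rng.uniform(-2.0, 2.0, size=(26, 4))
        # scale so u'u <= E everywhere
        E = 50.0
        norm = np.sqrt(np.sum(controls**2, axis=1)).max()
        controls *= np.sqrt(E) / norm
        r = _result(times, np.zeros((26, 14)), controls)
        assert joint_effort_integrals(r).sum() <= E * 0.5 + 1e-12


class TestCompareUniformConfigs:
    def test_identical_groups_not_significant(self, rng):
        base = rng.normal(1.0, 0.1, 20)
        res = compare_uniform_configs({1: base, 2: base.copy()})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert all(row["symbol"] == "()" for _, row in res["tukey"].iterrows())

    def test_separated_groups_highly_significant(self, rng):
        res = compare_uniform_configs({
            1: rng.normal(0.0, 0.1, 20),
            2: rng.normal(10.0, 0.1, 20),
        })
        assert res["F"] > 1e4
        assert res["p"] < 1e-10
        assert res["tukey"].iloc[0]["symbol"] == "***"

    def test_monotone_means_reproduce_first_vs_all_pattern(self, rng):
        """A strongly separated first group is *** against every other."""
        groups = {1: rng.normal(10.0, 0.5, 30)}
        for n in range(2, 7):
            groups[n] = rng.normal(4.0 - 0.3 * n, 0.5, 30)
        res = compare_uniform_configs(groups)
        tuk = res["tukey"]
        first_vs_all = tuk[tuk["n_a"] == 1]
        assert (first_vs_all["symbol"] == "***").all()

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_uniform_configs({1: [1.0, 2.0]})


class TestComparePaired:
    def test_identical_samples_give_t_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_paired(a, a)
        assert np.isnan(res["t"]) or res["t"] == pytest.approx(0.0)

    def test_constant_difference_degenerate(self):
        res = compare_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res["degenerate"] and res["p"] == 0.0

    def test_textbook_five_pair_example(self):
        """Hand-computed paired t: d = (1, 2, 3, 2, 2), mean 2, sd sqrt(0.5)."""
        a = [5.0, 7.0, 9.0, 8.0, 6.0]
        b = [4.0, 5.0, 6.0, 6.0, 4.0]
        d = np.array(a) - np.array(b)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = compare_paired(a, b)
        assert res["t"] == pytest.approx(t_expected, rel=1e-12)
        assert res["df"] == 4

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0], [1.0])


def test_significance_symbols():
    assert significance_symbol(1e-4) == "***"
    assert significance_symbol(5e-3) == "**"
    assert significance_symbol(0.03) == "*"
    assert significance_symbol(0.07) == "."
    assert significance_symbol(0.5) == "()"
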