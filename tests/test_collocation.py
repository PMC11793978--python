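"""Transcription structure, defect accuracy, solving and validation."""

import numpy as np
import pytest

from tailopt.collocation import (
    CollocationProblem,
    ConstraintBounds,
    TimeGrid,
    transcribe,
)
from tailopt.fixtures import zero_target
from tailopt.model import build_uniform_model
from tailopt.targets import sample_trajectory


@pytest.fixture(scope="module")
def zero_problem_1v():
    model = build_uniform_model(1)
    return CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.1))


class TestTimeGrid:
    def test_default_fast_grid(self):
        grid = TimeGrid(dt=0.02)
        assert grid.n_intervals == 25
        assert grid.knots[0] == 0.0 and grid.knots[-1] == pytest.approx(0.5)

    def test_reference_grid_has_125_intervals(self):
        assert TimeGrid(dt=0.004).n_intervals == 125

    def test_non_dividing_dt_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(dt=0.03)


class TestTranscription:
    def test_decision_variable_count(self):
        """(N+1)(2nq + nu) decision variables with knot-only controls."""
        model = build_uniform_model(1)
        prob = transcribe(model, zero_target(), grid=TimeGrid(dt=0.004))
        assert prob.n_vars == 126 * (2 * 5) + 126 * 2
        assert prob.N * prob.nx == 125 * 10  # defect equation count

    def test_defects_vanish_at_equilibrium(self, zero_problem_1v):
        z = zero_problem_1v.pack(
            np.zeros((zero_problem_1v.n_knots, zero_problem_1v.nx)),
            np.zeros((zero_problem_1v.n_knots, zero_problem_1v.nu)),
        )
        assert np.abs(zero_problem_1v.defects(z)).max() == 0.0

    def test_defect_jacobian_matches_finite_differences(self, rng):
        model = build_uniform_model(2)
        target = sample_trajectory(7)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.25))
        z = rng.uniform(-0.3, 0.3, prob.n_vars)
        J = prob.defects_jac(z).toarray()
        h = 1e-7
        for k in rng.choice(prob.n_vars, size=12, replace=False):
            e = np.zeros(prob.n_vars)
            e[k] = h
            fd = (prob.defects(z + e) - prob.defects(z - e)) / (2 * h)
            assert np.allclose(J[:, k], fd, atol=1e-5)

    def test_objective_gradient_matches_finite_differences(self, rng):
        model = build_uniform_model(1)
        target = sample_trajectory(3)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.25))
        z = rng.uniform(-0.2, 0.2, prob.n_vars)
        g = prob.objective_grad(z)
        h = 1e-7
        for k in rng.choice(prob.n_vars, size=10, replace=False):
            e = np.zeros(prob.n_vars)
            e[k] = h
            fd = (prob.objective(z + e) - prob.objective(z - e)) / (2 * h)
            assert g[k] == pytest.approx(fd, abs=1e-6)

    def test_defect_convergence_fourth_order(self):
        """Hermite–Simpson local accuracy ~ O(dt^4) on the true dynamics.

        Integrating the (nonlinear) dynamics to high precision and
        evaluating the defects of the exact trajectory at two grid
        resolutions shows the expected fourth-order decay.
        """
        model = build_uniform_model(1)
        from tailopt.dynamics import ChainDynamics

        dyn = ChainDynamics(model)
        u = np.array([1.5, -2.0])
        x0 = np.zeros(2 * model.nq)
        residuals = {}
        for dt in (0.05, 0.025):
            grid = TimeGrid(t0=0.0, tf=0.5, dt=dt)
            sol = dyn.integrate(x0, lambda t: u, 0.0, 0.5,
                                t_eval=grid.knots, rtol=1e-12, atol=1e-14)
            X = sol.y.T
            prob = CollocationProblem(model, zero_target(), grid=grid)
            U = np.tile(u, (grid.n_intervals + 1, 1))
            residuals[dt] = np.abs(prob.defects(prob.pack(X, U))).max()
        order = np.log2(residuals[0.05] / residuals[0.025])
        assert order > 3.5

    def test_grid_must_match_target_horizon(self):
        model = build_uniform_model(1)
        with pytest.raises(ValueError):
            CollocationProblem(model, zero_target(),
                               grid=TimeGrid(t0=0.0, tf=0.4, dt=0.1))


class TestCollisionConstraint:
    def test_straight_tail_is_collision_free(self):
        model = build_uniform_model(4)
        prob = CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.25))
        z = prob.pack(np.zeros((prob.n_knots, prob.nx)),
                      np.zeros((prob.n_knots, prob.nu)))
        assert prob.collision(z).max() < 0.0

    def test_sphere_pair_arithmetic(self):
        """g = (r_a + r_b) - dist for each torso/tail sphere pair."""
        model = build_uniform_model(1)
        prob = CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.25))
        q = np.zeros(model.nq)
        g = prob._collision_all(q, np.asarray(model.tail.lengths))
        dyn = prob.dyn
        torso, tail = dyn.collision_points(q)
        mobile = tail[prob._mobile_tail]
        expected = []
        for c_t in torso:
            for c_m in mobile:
                expected.append(
                    (0.25 + 0.07) - np.linalg.norm(c_t - c_m)
                )
        assert np.allclose(np.sort(g), np.sort(expected), atol=1e-12)

    def test_pair_count_excludes_fixed_base_sphere(self):
        """The tail-base sphere is rigid w.r.t. the torso; its distance to
        every torso sphere is constant, so those pairs carry no
        constraint and are excluded: ng = n_torso * (n_vertebrae mobile
        joints + tip)."""
        model = build_uniform_model(4)
        prob = CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.25))
        assert prob.ng == 3 * 4

    def test_collision_jacobian_matches_finite_differences(self, rng):
        model = build_uniform_model(2)
        prob = CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.25),
                                  optimize_lengths=True)
        z = prob.pack(
            rng.uniform(-0.4, 0.4, (prob.n_knots, prob.nx)),
            rng.uniform(-1, 1, (prob.n_knots, prob.nu)),
            np.array([0.6, 0.9]),
        )
        J = prob.collision_jac(z).toarray()
        h = 1e-7
        for k in rng.choice(prob.n_vars, size=10, replace=False):
            e = np.zeros(prob.n_vars)
            e[k] = h
            fd = (prob.collision(z + e) - prob.collision(z - e)) / (2 * h)
            assert np.allclose(J[:, k], fd, atol=1e-5)


class TestEffortConstraint:
    def test_values_at_knots_and_midpoints(self):
        model = build_uniform_model(1)
        prob = CollocationProblem(model, zero_target(), grid=TimeGrid(dt=0.25))
        U = np.array([[3.0, 4.0], [0.0, 0.0], [1.0, 0.0]])
        z = prob.pack(np.zeros((3, prob.nx)), U)
        eff = prob.effort(z)
        assert eff[:3] == pytest.approx([25.0, 0.0, 1.0])
        assert eff[3:] == pytest.approx([25.0 / 4.0, 0.25])

    def test_effort_cap_from_single_vertebra_bound(self):
        bounds = ConstraintBounds.from_model(build_uniform_model(1))
        # one 2-DOF joint at +/-5 Nm: max possible u'u = 2 * 25
        assert bounds.effort_cap == pytest.approx(50.0)


class TestInitialGuesses:
    def test_five_labelled_guesses(self, zero_problem_1v):
        guesses = zero_problem_1v.initial_guesses(seed=1)
        labels = [g[0] for g in guesses]
        assert labels == ["zeros", "linear", "random_1", "random_2", "random_3"]

    def test_zero_guess_satisfies_bounds_and_effort(self, zero_problem_1v):
        _, z = zero_problem_1v.initial_guesses(0)[0]
        lb, ub = zero_problem_1v.variable_bounds()
        assert np.all(z >= lb) and np.all(z <= ub)
        assert zero_problem_1v.effort(z).max() == 0.0

    def test_linear_guess_endpoints_match_target(self):
        model = build_uniform_model(1)
        target = sample_trajectory(5)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.1))
        _, z = prob.initial_guesses(0)[1]
        X, _, _ = prob.unpack(z)
        theta_f, _ = target.evaluate(np.array(0.5))
        assert np.allclose(X[0, :3], 0.0)
        assert np.allclose(X[-1, :3], theta_f)

    def test_random_guesses_reproducible_per_seed(self, zero_problem_1v):
        g1 = zero_problem_1v.initial_guesses(seed=4)
        g2 = zero_problem_1v.initial_guesses(seed=4)
        g3 = zero_problem_1v.initial_guesses(seed=5)
        assert np.array_equal(g1[2][1], g2[2][1])
        assert not np.array_equal(g1[2][1], g3[2][1])


class TestSolveAndValidate:
    def test_zero_target_solves_to_zero_cost(self, zero_problem_1v):
        res = zero_problem_1v.solve(
            zero_problem_1v.initial_guesses(0)[0][1],
            method="trust-constr", maxiter=50,
        )
        assert res.cost == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.controls, 0.0, atol=1e-6)
        assert res.solver_status != "failed"

    def test_multistart_returns_minimum(self):
        model = build_uniform_model(1)
        target = sample_trajectory(11)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.1))
        individual = [
            prob.solve(z, init_label=lbl, method="trust-constr", maxiter=60)
            for lbl, z in prob.initial_guesses(0)[:3]
        ]
        best = prob.multistart(seed=0, n_starts=3, method="trust-constr",
                               maxiter=60)
        feasible_costs = [r.cost for r in individual
                          if r.solver_status != "failed"]
        assert best.cost == pytest.approx(min(feasible_costs), abs=1e-12)

    def test_solution_satisfies_constraints_on_recheck(self):
        model = build_uniform_model(2)
        target = sample_trajectory(13)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.05))
        res = prob.solve(prob.initial_guesses(0)[1][1],
                         method="trust-constr", maxiter=200)
        z = prob.pack(res.states, res.controls)
        assert prob.constraint_violation(z) <= 1e-6
        assert res.cost == pytest.approx(prob.objective(z), abs=1e-8)

    def test_validation_of_zero_solution_is_machine_level(self, zero_problem_1v):
        res = zero_problem_1v.solve(
            zero_problem_1v.initial_guesses(0)[0][1],
            method="trust-constr", maxiter=50,
        )
        assert zero_problem_1v.validate(res) < 1e-9

    def test_validation_deviation_shrinks_with_dt(self):
        model = build_uniform_model(1)
        target = sample_trajectory(17)
        devs = {}
        for dt in (0.1, 0.05):
            prob = CollocationProblem(model, target, grid=TimeGrid(dt=dt))
            res = prob.solve(prob.initial_guesses(0)[1][1],
                             method="trust-constr", maxiter=250)
            devs[dt] = prob.validate(res)
        assert devs[0.05] < devs[0.1]

    def test_corrupted_controls_flagged_by_validation(self):
        model = build_uniform_model(1)
        target = sample_trajectory(19)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.05))
        res = prob.solve(prob.initial_guesses(0)[1][1],
                         method="trust-constr", maxiter=150)
        good = prob.validate(res)
        res.controls[:] = np.clip(res.controls + 3.0, -5.0, 5.0)
        assert prob.validate(res) > max(10 * good, 1e-3)


class TestRollout:
    def test_reduced_solve_of_zero_target(self):
        """The reduced-space solver (states eliminated via the implicit
        rollout) also recognises the zero target as exactly reachable."""
        prob = CollocationProblem(build_uniform_model(1), zero_target(),
                                  grid=TimeGrid(dt=0.1))
        res = prob.solve(prob.initial_guesses(0)[0][1], method="reduced",
                         maxiter=30)
        assert res.cost == pytest.approx(0.0, abs=1e-8)
        assert res.solver_status != "failed"

    def test_rollout_satisfies_defects(self, rng):
        model = build_uniform_model(2)
        target = sample_trajectory(23)
        prob = CollocationProblem(model, target, grid=TimeGrid(dt=0.05))
        U = rng.uniform(-1.0, 1.0, (prob.n_knots, prob.nu))
        X = prob.rollout(U)
        z = prob.pack(X, U)
        assert np.abs(prob.defects(z)).max() < 1e-9
        assert np.allclose(X[0], 0.0)
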