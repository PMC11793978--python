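"""Dynamics oracles: symmetry, conservation laws, independent derivations."""

import numpy as np
import pytest

from tailopt.dynamics import ChainDynamics
from tailopt.model import build_uniform_model, prism_inertia


def random_state(dyn, rng, angle=0.5, rate=2.0):
    q = rng.uniform(-angle, angle, dyn.nq)
    qdot = rng.uniform(-rate, rate, dyn.nq)
    return q, qdot


class TestMassMatrix:
    def test_symmetry_and_positive_definiteness(self, dyn_2v, rng):
        q = rng.uniform(-1.0, 1.0, size=(100, dyn_2v.nq))
        M = dyn_2v.mass_matrix(q)
        assert np.abs(M - np.swapaxes(M, -1, -2)).max() < 1e-10
        assert min(np.linalg.eigvalsh(Mi).min() for Mi in M) > 0.0

    def test_straight_single_vertebra_composite_inertia(self, model_1v):
        """Base block equals the torso+tail composite inertia (parallel axis)."""
        dyn = ChainDynamics(model_1v)
        M = dyn.mass_matrix(np.zeros(model_1v.nq))
        torso_inertia = prism_inertia(model_1v.torso)
        tail_geom = model_1v.tail.geometries()[0]
        tail_inertia = prism_inertia(tail_geom)
        m = tail_geom.mass
        d = model_1v.torso.length / 2.0 + tail_geom.length / 2.0  # COM offset, -y
        composite = np.array(torso_inertia)
        composite += tail_inertia
        composite[0, 0] += m * d**2  # roll axis (x): lever arm d
        composite[2, 2] += m * d**2  # yaw axis (z): lever arm d
        # pitch axis (y) passes through the tail COM: no parallel-axis term
        assert np.allclose(M[:3, :3], np.diag(np.diag(composite)), atol=1e-9)
        assert np.allclose(M[:3, :3], composite, atol=1e-9)


class TestBiasForces:
    def test_zero_velocity_gives_zero_bias(self, dyn_2v, rng):
        q = rng.uniform(-1.0, 1.0, size=(10, dyn_2v.nq))
        assert np.all(dyn_2v.bias_forces(q, np.zeros_like(q)) == 0.0)

    def test_quadratic_velocity_scaling(self, dyn_2v, rng):
        q, qdot = random_state(dyn_2v, rng)
        h1 = dyn_2v.bias_forces(q, qdot)
        h2 = dyn_2v.bias_forces(q, 2.0 * qdot)
        assert np.allclose(h2, 4.0 * h1, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2])
    def test_bias_consistent_with_mass_matrix_derivatives(self, n, rng):
        """Euler–Lagrange oracle: C(q, q̇) from finite differences of M.

        With T = q̇ᵀM(q)q̇/2 and no gravity, the bias force is
        C_i = Σ_jk (∂M_ij/∂q_k − ∂M_jk/∂q_i / 2) q̇_j q̇_k — an
        independent derivation using only the mass matrix.
        """
        dyn = ChainDynamics(build_uniform_model(n))
        h = 1e-6
        for _ in range(5):
            q, qdot = random_state(dyn, rng)
            dM = np.stack([
                (dyn.mass_matrix(q + h * e) - dyn.mass_matrix(q - h * e))
                / (2 * h)
                for e in np.eye(dyn.nq)
            ], axis=0)  # (k, i, j) = dM_ij/dq_k
            C = (np.einsum("kij,j,k->i", dM, qdot, qdot)
                 - 0.5 * np.einsum("ijk,j,k->i", dM, qdot, qdot))
            assert np.allclose(dyn.bias_forces(q, qdot), C, atol=1e-5)


class TestForwardDynamics:
    def test_equilibrium(self, dyn_2v):
        qdd = dyn_2v.forward_dynamics(
            np.zeros(dyn_2v.nq), np.zeros(dyn_2v.nq), np.zeros(dyn_2v.nu)
        )
        assert np.all(qdd == 0.0)

    def test_base_receives_no_torque(self, dyn_2v, rng):
        q, qdot = random_state(dyn_2v, rng)
        u = rng.uniform(-5.0, 5.0, dyn_2v.nu)
        qdd = dyn_2v.forward_dynamics(q, qdot, u)
        M = dyn_2v.mass_matrix(q)
        H = dyn_2v.bias_forces(q, qdot)
        generalized = M @ qdd + H
        assert np.allclose(generalized[:3], 0.0, atol=1e-10)
        assert np.allclose(generalized[3:], u, atol=1e-10)

    def test_dimension_mismatch_raises(self, dyn_2v):
        with pytest.raises(ValueError):
            dyn_2v.forward_dynamics(
                np.zeros(dyn_2v.nq), np.zeros(dyn_2v.nq), np.zeros(3)
            )

    def test_against_symbolic_lagrangian_oracle(self, rng):
        """Independent Lagrangian oracle (single vertebra).

        The oracle builds the kinetic energy T(q, q̇) from explicit
        rotation matrices in sympy — a construction disjoint from the
        Newton–Euler recursion under test.  Because T is exactly
        quadratic in q̇, the mass matrix follows from exact second
        differences of T, and the bias from the Christoffel form with
        finite differences in q; q̈ = M⁻¹(τ − C) is then compared with
        the implementation.
        """
        sp = pytest.importorskip("sympy")

        model = build_uniform_model(1)
        dyn = ChainDynamics(model)
        qs = sp.symbols("q_0:5")
        qds = sp.symbols("qd_0:5")
        roll, pitch, yaw, tp, ty = qs

        def rx(a):
            return sp.Matrix([[1, 0, 0],
                              [0, sp.cos(a), -sp.sin(a)],
                              [0, sp.sin(a), sp.cos(a)]])

        def ry(a):
            return sp.Matrix([[sp.cos(a), 0, sp.sin(a)],
                              [0, 1, 0],
                              [-sp.sin(a), 0, sp.cos(a)]])

        def rz(a):
            return sp.Matrix([[sp.cos(a), -sp.sin(a), 0],
                              [sp.sin(a), sp.cos(a), 0],
                              [0, 0, 1]])

        R_torso = rz(yaw) * ry(pitch) * rx(roll)
        R_tail = R_torso * rx(tp) * rz(ty)

        def ddt(expr):
            return sum(expr.diff(qi) * qdi for qi, qdi in zip(qs, qds))

        def omega_world(R):
            Rdot = R.applyfunc(ddt)
            W = Rdot * R.T
            return sp.Matrix([W[2, 1], W[0, 2], W[1, 0]])

        torso_I = sp.diag(*[float(v) for v in np.diag(prism_inertia(model.torso))])
        tail_geom = model.tail.geometries()[0]
        tail_I = sp.diag(*[float(v) for v in np.diag(prism_inertia(tail_geom))])
        w_torso = omega_world(R_torso)
        w_tail = omega_world(R_tail)
        p_tail = (R_torso * sp.Matrix([0, -sp.Rational(1, 2), 0])
                  + R_tail * sp.Matrix([0, -sp.Rational(3, 4), 0]))
        v_tail = p_tail.applyfunc(ddt)
        T = (
            (w_torso.T * (R_torso * torso_I * R_torso.T) * w_torso)[0, 0] / 2
            + tail_geom.mass * (v_tail.T * v_tail)[0, 0] / 2
            + (w_tail.T * (R_tail * tail_I * R_tail.T) * w_tail)[0, 0] / 2
        )
        f_T = sp.lambdify(qs + qds, T, "numpy", cse=True)

        def M_oracle(q):
            # exact for a quadratic form: polarization identity at h = 1
            e = np.eye(5)
            T0 = f_T(*q, *np.zeros(5))
            M = np.empty((5, 5))
            for i in range(5):
                for j in range(i + 1):
                    Tij = f_T(*q, *(e[i] + e[j]))
                    Ti = f_T(*q, *e[i])
                    Tj = f_T(*q, *e[j])
                    M[i, j] = M[j, i] = Tij - Ti - Tj + T0
            return M

        h = 1e-6
        for _ in range(5):
            q, qdot = random_state(dyn, rng, angle=0.8, rate=3.0)
            u = rng.uniform(-5.0, 5.0, dyn.nu)
            tau = np.concatenate([np.zeros(3), u])
            M_o = M_oracle(q)
            dM = np.stack([
                (M_oracle(q + h * e) - M_oracle(q - h * e)) / (2 * h)
                for e in np.eye(5)
            ], axis=0)
            C_o = (np.einsum("kij,j,k->i", dM, qdot, qdot)
                   - 0.5 * np.einsum("ijk,j,k->i", dM, qdot, qdot))
            qdd_oracle = np.linalg.solve(M_o, tau - C_o)
            qdd = dyn.forward_dynamics(q, qdot, u)
            assert np.allclose(qdd, qdd_oracle, rtol=1e-6, atol=1e-6)


class TestDerivedQuantities:
    def test_tip_velocity_zero_at_rest(self, dyn_2v, rng):
        q = rng.uniform(-1.0, 1.0, dyn_2v.nq)
        vel, speed = dyn_2v.tip_velocity(q, np.zeros(dyn_2v.nq))
        assert np.allclose(vel, 0.0) and speed == 0.0

    def test_tip_speed_lever_arm(self, model_1v):
        """Pure base yaw at rate w: tip speed = w * (distance to tip)."""
        dyn = ChainDynamics(model_1v)
        q = np.zeros(dyn.nq)
        qdot = np.zeros(dyn.nq)
        w = 1.7
        qdot[2] = w  # yaw rate
        lever = model_1v.torso.length / 2.0 + model_1v.tail.lengths[0]
        _, speed = dyn.tip_velocity(q, qdot)
        assert speed == pytest.approx(w * lever, rel=1e-12)

    def test_tip_velocity_matches_position_differences(self, dyn_2v, rng):
        x0 = np.concatenate([rng.uniform(-0.3, 0.3, dyn_2v.nq),
                             rng.uniform(-1.0, 1.0, dyn_2v.nq)])
        u = rng.uniform(-2.0, 2.0, dyn_2v.nu)
        ts = np.linspace(0.0, 0.2, 161)
        sol = dyn_2v.integrate(x0, lambda t: u, 0.0, 0.2, t_eval=ts,
                               rtol=1e-10, atol=1e-12)
        X = sol.y.T
        nq = dyn_2v.nq
        pos = dyn_2v.tip_position(X[:, :nq])
        vel, _ = dyn_2v.tip_velocity(X[:, :nq], X[:, nq:])
        fd = np.gradient(pos, ts, axis=0)
        # central differences on the interior points
        assert np.allclose(vel[1:-1], fd[1:-1], atol=1e-4)


class TestConservationLaws:
    def test_momentum_and_energy_conserved_without_input(self, dyn_2v, rng):
        x0 = np.concatenate([rng.uniform(-0.3, 0.3, dyn_2v.nq),
                             rng.uniform(-1.0, 1.0, dyn_2v.nq)])
        sol = dyn_2v.integrate(
            x0, lambda t: np.zeros(dyn_2v.nu), 0.0, 0.5,
            t_eval=np.linspace(0.0, 0.5, 11),
        )
        X = sol.y.T
        nq = dyn_2v.nq
        L = dyn_2v.angular_momentum(X[:, :nq], X[:, nq:])
        E = dyn_2v.kinetic_energy(X[:, :nq], X[:, nq:])
        assert np.abs(L - L[0]).max() / np.abs(L[0]).max() < 1e-6
        assert np.abs(E - E[0]).max() / E[0] < 1e-6

    def test_momentum_conserved_even_with_tail_torques(self, dyn_2v, rng):
        """Internal torques exert no moment about the free base pin."""
        x0 = np.concatenate([rng.uniform(-0.3, 0.3, dyn_2v.nq),
                             rng.uniform(-1.0, 1.0, dyn_2v.nq)])
        u = np.array([3.0, -2.0, 1.5, 0.7])
        sol = dyn_2v.integrate(x0, lambda t: u, 0.0, 0.3,
                               t_eval=np.linspace(0.0, 0.3, 7))
        X = sol.y.T
        nq = dyn_2v.nq
        L = dyn_2v.angular_momentum(X[:, :nq], X[:, nq:])
        scale = max(np.abs(L[0]).max(), 1e-9)
        assert np.abs(L - L[0]).max() / scale < 1e-6

    def test_work_energy_balance_under_actuation(self, dyn_2v, rng):
        x0 = np.concatenate([rng.uniform(-0.2, 0.2, dyn_2v.nq),
                             rng.uniform(-0.5, 0.5, dyn_2v.nq)])

        def control(t):
            return np.array([2.0 * np.sin(8 * t), -1.0, 0.5, np.cos(5 * t)])

        ts = np.linspace(0.0, 0.3, 301)
        sol = dyn_2v.integrate(x0, control, 0.0, 0.3, t_eval=ts,
                               rtol=1e-10, atol=1e-12)
        X = sol.y.T
        nq = dyn_2v.nq
        E = dyn_2v.kinetic_energy(X[:, :nq], X[:, nq:])
        power = np.array([
            X[i, nq + 3:] @ control(ts[i]) for i in range(len(ts))
        ])
        work = np.concatenate([[0.0], np.cumsum(
            0.5 * (power[1:] + power[:-1]) * np.diff(ts)
        )])
        assert np.abs((E - E[0]) - work).max() < 1e-4 * max(1.0, E.max())


class TestIntegrate:
    def test_rest_stays_at_rest(self, dyn_2v):
        x0 = np.zeros(2 * dyn_2v.nq)
        sol = dyn_2v.integrate(x0, lambda t: np.zeros(dyn_2v.nu), 0.0, 0.5,
                               t_eval=[0.25, 0.5])
        assert np.allclose(sol.y, 0.0, atol=1e-12)

    def test_agrees_with_fixed_step_rk4(self, dyn_2v, rng):
        x0 = np.concatenate([rng.uniform(-0.2, 0.2, dyn_2v.nq),
                             rng.uniform(-0.5, 0.5, dyn_2v.nq)])
        u = rng.uniform(-2.0, 2.0, dyn_2v.nu)
        sol = dyn_2v.integrate(x0, lambda t: u, 0.0, 0.1, t_eval=[0.1],
                               rtol=1e-10, atol=1e-12)
        # independent fixed-step RK4
        dt = 1e-4
        x = x0.copy()
        for _ in range(1000):
            k1 = dyn_2v.f(x, u)
            k2 = dyn_2v.f(x + dt / 2 * k1, u)
            k3 = dyn_2v.f(x + dt / 2 * k2, u)
            k4 = dyn_2v.f(x + dt * k3, u)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert np.allclose(sol.y[:, -1], x, atol=1e-6)
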