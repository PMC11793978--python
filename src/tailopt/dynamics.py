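"""Articulated rigid-body dynamics of the torso + tail chain.

The model is a serial chain of single-DOF revolute joints: three
unactuated base joints (yaw about z, pitch about y, roll about x —
the intrinsic Z-Y-X decomposition of the torso orientation) followed by
a pitch/yaw pair per vertebra.  Gravity is exactly zero: inertial
manoeuvring relies on conservation of angular momentum, which is
independent of gravity, so the torso is pinned at a point and rotates
only in reaction to tail motion.

All kernels are written dtype-generically and broadcast over arbitrary
leading batch axes, which serves two purposes:

* whole trajectories are evaluated in one vectorized call during
  collocation, and
* exact derivatives are obtained by complex-step differentiation
  (perturbing inputs by ``1j * h`` and reading ``imag/h``), which is
  accurate to machine precision because no operation in the evaluation
  path conjugates or takes magnitudes.

Externally the configuration vector is
``q = (roll, pitch, yaw, pitch_1, yaw_1, ..., pitch_n, yaw_n)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelSpec, prism_inertia

__all__ = [
    "ChainDynamics",
    "mass_matrix",
    "bias_forces",
    "forward_dynamics",
    "tip_velocity",
    "angular_momentum",
    "kinetic_energy",
    "integrate",
]

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}

#: complex-step size; results are exact to double precision
_CS_H = 1e-100


def _hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix, batched over leading axes."""
    shape = v.shape[:-1] + (3, 3)
    out = np.zeros(shape, dtype=v.dtype)
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def _axis_rotation(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation about a fixed unit axis, batched over angle."""
    c = np.cos(angle)[..., None, None]
    s = np.sin(angle)[..., None, None]
    K = _hat(axis)
    eye = np.eye(3)
    return eye + s * K + (1.0 - c) * (K @ K)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3-vector cross product over the last axis.

    Hand-rolled instead of np.cross: it is called in the innermost
    dynamics loops and the direct formula is several times faster for
    small batches (and equally dtype-generic).
    """
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    return np.stack(
        [a1 * b2 - a2 * b1, a2 * b0 - a0 * b2, a0 * b1 - a1 * b0], axis=-1
    )


class ChainDynamics:
    """Dynamics evaluator for one :class:`~tailopt.model.ModelSpec`.

    Vertebral lengths may be overridden per call (``lengths=``), which
    re-derives per-vertebra mass, inertia and joint placement at uniform
    density — the hook used by the morphology co-design problem, where
    lengths are decision variables and derivatives with respect to them
    are taken by complex step through this same code path.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.n = model.n_vertebrae
        self.nq = model.nq
        self.nu = model.nu
        # chain (internal) joint order: yaw(z), pitch(y), roll(x), then
        # pitch_i(x), yaw_i(z) per vertebra; q_chain = q_ext[perm]
        self._perm = np.array([2, 1, 0] + list(range(3, self.nq)))
        self._invperm = np.argsort(self._perm)
        axes = ["z", "y", "x"]
        for _ in range(self.n):
            axes += ["x", "z"]
        self._axes = [_AXES[a] for a in axes]
        self._torso_frame = 2
        # frame index of vertebra i's body (its yaw joint frame)
        self._vert_frames = [4 + 2 * i for i in range(self.n)]
        # linear density of the tail (kg/m), fixed by total mass/length
        self._rho = model.tail.total_mass / model.tail.total_length
        self._default_lengths = np.asarray(model.tail.lengths, dtype=float)

    # -- structure -----------------------------------------------------

    def _geometry(self, lengths):
        """Joint offsets, body COM offsets, masses and inertias.

        Everything is computed from ``lengths`` so that complex-valued
        lengths propagate (for derivatives in the co-design problem).
        """
        lengths = np.asarray(lengths)
        model = self.model
        cs = model.tail.cross_section
        dtype = np.result_type(lengths.dtype, float)
        batch = lengths.shape[:-1]

        njoints = 3 + 2 * self.n
        offsets = np.zeros(batch + (njoints, 3), dtype=dtype)
        # first tail joint at the torso's posterior end face
        offsets[..., 3, 1] = -model.torso.length / 2.0
        for i in range(1, self.n):
            offsets[..., 3 + 2 * i, 1] = -lengths[..., i - 1]

        nbodies = 1 + self.n
        coms = np.zeros(batch + (nbodies, 3), dtype=dtype)
        masses = np.zeros(batch + (nbodies,), dtype=dtype)
        inertias = np.zeros(batch + (nbodies, 3, 3), dtype=dtype)
        masses[..., 0] = model.torso.mass
        inertias[..., 0, :, :] = prism_inertia(model.torso)
        for i in range(self.n):
            li = lengths[..., i]
            mi = self._rho * li
            masses[..., 1 + i] = mi
            coms[..., 1 + i, 1] = -li / 2.0
            inertias[..., 1 + i, 0, 0] = mi / 12.0 * (li**2 + cs**2)
            inertias[..., 1 + i, 1, 1] = mi / 12.0 * (cs**2 + cs**2)
            inertias[..., 1 + i, 2, 2] = mi / 12.0 * (cs**2 + li**2)
        return offsets, coms, masses, inertias

    # -- kinematics ----------------------------------------------------

    def _fk(self, q, lengths=None):
        """Forward kinematics in chain order.

        Returns per-joint world rotations ``R`` (..., nj, 3, 3), origins
        ``p`` (..., nj, 3) and world joint axes ``a`` (..., nj, 3).
        """
        q = np.asarray(q)
        if lengths is None:
            lengths = self._default_lengths
        offsets, _, _, _ = self._geometry(lengths)
        qc = q[..., self._perm]
        dtype = np.result_type(q.dtype, offsets.dtype, float)
        batch = np.broadcast_shapes(q.shape[:-1], offsets.shape[:-2])
        nj = len(self._axes)
        R = np.zeros(batch + (nj, 3, 3), dtype=dtype)
        p = np.zeros(batch + (nj, 3), dtype=dtype)
        a = np.zeros(batch + (nj, 3), dtype=dtype)
        R_parent = np.broadcast_to(np.eye(3), batch + (3, 3)).astype(dtype)
        p_parent = np.zeros(batch + (3,), dtype=dtype)
        for j, axis in enumerate(self._axes):
            s = (R_parent @ offsets[..., j, :, None])[..., 0]
            p_j = p_parent + s
            R_j = R_parent @ _axis_rotation(axis, qc[..., j])
            a[..., j, :] = (R_parent @ axis[:, None])[..., 0]
            R[..., j, :, :] = R_j
            p[..., j, :] = p_j
            R_parent, p_parent = R_j, p_j
        return R, p, a

    def _body_jacobians(self, R, p, a, coms):
        """World COM positions and 6xnq body Jacobians (chain order)."""
        nq = self.nq
        bodies = [self._torso_frame] + self._vert_frames
        batch = R.shape[:-3]
        dtype = R.dtype
        nb = len(bodies)
        c = np.zeros(batch + (nb, 3), dtype=dtype)
        Jv = np.zeros(batch + (nb, 3, nq), dtype=dtype)
        Jw = np.zeros(batch + (nb, 3, nq), dtype=dtype)
        for b, f in enumerate(bodies):
            cb = p[..., f, :] + (R[..., f, :, :] @ coms[..., b, :, None])[..., 0]
            c[..., b, :] = cb
            aj = a[..., : f + 1, :]                       # (..., f+1, 3)
            lever = cb[..., None, :] - p[..., : f + 1, :]
            Jw[..., b, :, : f + 1] = np.swapaxes(aj, -1, -2)
            Jv[..., b, :, : f + 1] = np.swapaxes(_cross(aj, lever), -1, -2)
        return c, Jv, Jw

    # -- dynamics quantities --------------------------------------------

    def mass_matrix(self, q, lengths=None):
        """Joint-space mass-inertia matrix M(q), external coordinate order."""
        M, _ = self._mass_and_bias(q, None, lengths)
        return M

    def _mass_and_bias(self, q, qdot, lengths=None):
        """M(q) and, when qdot is given, H(q, q̇) sharing one FK pass."""
        if lengths is None:
            lengths = self._default_lengths
        with_bias = qdot is not None
        if with_bias:
            (R, p, a, w, dw, v, acc, coms, masses, inertias) = (
                self._velocity_recursion(q, qdot, lengths)
            )
        else:
            R, p, a = self._fk(q, lengths)
            _, coms, masses, inertias = self._geometry(lengths)
        c, Jv, Jw = self._body_jacobians(R, p, a, coms)
        nq = self.nq
        batch = R.shape[:-3]
        M = np.zeros(batch + (nq, nq), dtype=R.dtype)
        if with_bias:
            hbatch = np.broadcast_shapes(batch, w.shape[:-2])
            H = np.zeros(hbatch + (nq,), dtype=w.dtype)
        else:
            H = None
        bodies = [self._torso_frame] + self._vert_frames
        for b, f in enumerate(bodies):
            Rb = R[..., f, :, :]
            Iw = Rb @ inertias[..., b, :, :] @ np.swapaxes(Rb, -1, -2)
            jv = Jv[..., b, :, :]
            jw = Jw[..., b, :, :]
            jvT = np.swapaxes(jv, -1, -2)
            jwT = np.swapaxes(jw, -1, -2)
            M = M + masses[..., b, None, None] * (jvT @ jv)
            M = M + jwT @ (Iw @ jw)
            if with_bias:
                r = c[..., b, :] - p[..., f, :]
                wf = w[..., f, :]
                dwf = dw[..., f, :]
                c_acc = (
                    acc[..., f, :] + _cross(dwf, r) + _cross(wf, _cross(wf, r))
                )
                F = masses[..., b, None] * c_acc
                N = (Iw @ dwf[..., None])[..., 0] + _cross(
                    wf, (Iw @ wf[..., None])[..., 0]
                )
                H = H + (jvT @ F[..., None])[..., 0] + (jwT @ N[..., None])[..., 0]
        ip = self._invperm
        M = M[..., ip[:, None], ip[None, :]]
        if with_bias:
            H = H[..., self._invperm]
        return M, H

    def _velocity_recursion(self, q, qdot, lengths):
        """Velocities and zero-q̈ accelerations of every joint frame."""
        R, p, a = self._fk(q, lengths)
        offsets, coms, masses, inertias = self._geometry(lengths)
        qc = np.asarray(qdot)[..., self._perm]
        batch = np.broadcast_shapes(R.shape[:-3], qc.shape[:-1])
        dtype = np.result_type(R.dtype, qc.dtype)
        nj = len(self._axes)
        w = np.zeros(batch + (nj, 3), dtype=dtype)
        dw = np.zeros(batch + (nj, 3), dtype=dtype)
        v = np.zeros(batch + (nj, 3), dtype=dtype)
        acc = np.zeros(batch + (nj, 3), dtype=dtype)
        w_p = np.zeros(batch + (3,), dtype=dtype)
        dw_p = np.zeros(batch + (3,), dtype=dtype)
        v_p = np.zeros(batch + (3,), dtype=dtype)
        acc_p = np.zeros(batch + (3,), dtype=dtype)
        R_parent = np.broadcast_to(np.eye(3), batch + (3, 3)).astype(dtype)
        for j in range(nj):
            s = (R_parent @ offsets[..., j, :, None])[..., 0]
            aj = a[..., j, :]
            qdj = qc[..., j, None]
            v_j = v_p + _cross(w_p, s)
            acc_j = acc_p + _cross(dw_p, s) + _cross(w_p, _cross(w_p, s))
            w_j = w_p + aj * qdj
            dw_j = dw_p + _cross(w_p, aj) * qdj
            w[..., j, :] = w_j
            dw[..., j, :] = dw_j
            v[..., j, :] = v_j
            acc[..., j, :] = acc_j
            w_p, dw_p, v_p, acc_p = w_j, dw_j, v_j, acc_j
            R_parent = R[..., j, :, :]
        return R, p, a, w, dw, v, acc, coms, masses, inertias

    def bias_forces(self, q, qdot, lengths=None):
        """Coriolis/centrifugal generalized forces H(q, q̇) (no gravity).

        Newton–Euler with q̈ = 0: body forces from velocity-product
        accelerations, projected back through the body Jacobians.
        """
        _, H = self._mass_and_bias(q, qdot, lengths)
        return H

    def forward_dynamics(self, q, qdot, u, lengths=None):
        """q̈ solving M q̈ + H = [0, 0, 0, uᵀ]ᵀ (unactuated base)."""
        q = np.asarray(q)
        u = np.asarray(u)
        if u.shape[-1] != self.nu:
            raise ValueError(f"u has dimension {u.shape[-1]}, expected {self.nu}")
        M, H = self._mass_and_bias(q, qdot, lengths)
        tau = np.zeros(np.broadcast_shapes(q.shape[:-1], u.shape[:-1]) + (self.nq,),
                       dtype=np.result_type(M.dtype, u.dtype))
        tau[..., 3:] = u
        rhs = tau - H
        return np.linalg.solve(M, rhs[..., None])[..., 0]

    # -- first-order form and derivatives --------------------------------

    def f(self, x, u, lengths=None):
        """State derivative ẋ = (q̇, q̈) of the first-order system."""
        x = np.asarray(x)
        nq = self.nq
        q, qdot = x[..., :nq], x[..., nq:]
        qddot = self.forward_dynamics(q, qdot, u, lengths)
        return np.concatenate([np.broadcast_to(qdot, qddot.shape), qddot], axis=-1)

    def f_jac(self, x, u, lengths=None, with_lengths=False):
        """Exact Jacobians of f, mixing closed forms and complex step.

        The structure of M(q) q̈ + H(q, q̇) = S u is exploited:

        * ∂q̈/∂u = M⁻¹ Sᵀ directly (one multi-RHS solve);
        * ∂q̈/∂q̇ = −M⁻¹ ∂H/∂q̇ with ∂H/∂q̇ by complex step through the
          bias recursion only (M does not depend on q̇);
        * ∂q̈/∂q (and ∂q̈/∂L) by complex step through the full dynamics.

        Returns ``(fx, fu)`` with shapes (..., 2nq, 2nq) and
        (..., 2nq, nu); with ``with_lengths=True`` additionally returns
        ``fL`` (..., 2nq, n).
        """
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        nq, nx, nu, n = self.nq, 2 * self.nq, self.nu, self.n
        if lengths is None:
            lengths = self._default_lengths
        lengths = np.asarray(lengths, dtype=float)
        batch = np.broadcast_shapes(x.shape[:-1], u.shape[:-1],
                                    lengths.shape[:-1])
        q, qdot = x[..., :nq], x[..., nq:]
        h = _CS_H
        nL = n if with_lengths else 0

        M, H = self._mass_and_bias(q, qdot, lengths)
        tau = np.zeros(batch + (nq,))
        tau = tau + 0.0
        tau[..., 3:] = u
        qddot = np.linalg.solve(M, (tau - H)[..., None])[..., 0]

        # complex step through M and H for q (and length) directions
        D = nq + nL
        Q = np.repeat(q[..., None, :].astype(complex), D, axis=-2)
        Lb = np.broadcast_to(lengths, batch + (n,))
        Lc = np.repeat(Lb[..., None, :].astype(complex), D, axis=-2)
        idx = np.arange(nq)
        Q[..., idx, idx] += 1j * h
        if nL:
            idx = np.arange(nL)
            Lc[..., nq + idx, idx] += 1j * h
        Mc, Hc = self._mass_and_bias(Q, qdot[..., None, :], Lc)
        dM = Mc.imag / h                       # (..., D, nq, nq)
        dH = Hc.imag / h                       # (..., D, nq)
        # d(qddot) = -M^{-1} (dM qddot + dH) for q/L perturbations
        rhs = -(dM @ qddot[..., None, :, None])[..., 0] - dH
        dqdd_q = np.linalg.solve(M[..., None, :, :], rhs[..., None])[..., 0]

        # bias-only complex step for velocity directions
        V = np.repeat(qdot[..., None, :].astype(complex), nq, axis=-2)
        idx = np.arange(nq)
        V[..., idx, idx] += 1j * h
        _, Hv = self._mass_and_bias(q[..., None, :], V, Lb[..., None, :])
        dHv = Hv.imag / h                      # (..., nq_dir, nq)
        dqdd_v = np.linalg.solve(M[..., None, :, :], -dHv[..., None])[..., 0]

        # exact control directions
        Minv_S = np.linalg.solve(M, np.broadcast_to(
            np.eye(nq)[:, 3:], batch + (nq, nu)).copy())

        fx = np.zeros(batch + (nx, nx))
        fx[..., :nq, nq:] = np.eye(nq)
        fx[..., nq:, :nq] = np.swapaxes(dqdd_q[..., :nq, :], -1, -2)
        fx[..., nq:, nq:] = np.swapaxes(dqdd_v, -1, -2)
        fu = np.zeros(batch + (nx, nu))
        fu[..., nq:, :] = Minv_S
        if with_lengths:
            fL = np.zeros(batch + (nx, nL))
            fL[..., nq:, :] = np.swapaxes(dqdd_q[..., nq:, :], -1, -2)
            return fx, fu, fL
        return fx, fu

    # -- derived quantities ----------------------------------------------

    def tip_position(self, q, lengths=None):
        """World position of the most distal point of the last vertebra."""
        if lengths is None:
            lengths = self._default_lengths
        lengths = np.asarray(lengths)
        R, p, _ = self._fk(q, lengths)
        f = self._vert_frames[-1]
        tip_local = np.zeros(lengths.shape[:-1] + (3,), dtype=R.dtype)
        tip_local[..., 1] = -lengths[..., -1]
        return p[..., f, :] + (R[..., f, :, :] @ tip_local[..., None])[..., 0]

    def tip_velocity(self, q, qdot, lengths=None):
        """World linear velocity of the tail tip and its norm."""
        if lengths is None:
            lengths = self._default_lengths
        lengths = np.asarray(lengths, dtype=float)
        (R, p, a, w, dw, v, acc, coms, masses, inertias) = (
            self._velocity_recursion(q, qdot, lengths)
        )
        f = self._vert_frames[-1]
        tip_local = np.zeros(lengths.shape[:-1] + (3,), dtype=R.dtype)
        tip_local[..., 1] = -lengths[..., -1]
        r = (R[..., f, :, :] @ tip_local[..., None])[..., 0]
        vel = v[..., f, :] + _cross(w[..., f, :], r)
        speed = np.sqrt(np.sum(vel * vel, axis=-1))
        return vel, speed

    def angular_momentum(self, q, qdot, lengths=None):
        """Total angular momentum about the fixed base point (world frame).

        The base pin transmits force but no torque and the system is
        torque-free externally, so this is conserved along any motion,
        with or without internal (tail) actuation.
        """
        if lengths is None:
            lengths = self._default_lengths
        (R, p, a, w, dw, v, acc, coms, masses, inertias) = (
            self._velocity_recursion(q, qdot, lengths)
        )
        bodies = [self._torso_frame] + self._vert_frames
        batch = R.shape[:-3]
        Ltot = np.zeros(batch + (3,), dtype=R.dtype)
        for b, f in enumerate(bodies):
            Rb = R[..., f, :, :]
            Iw = Rb @ inertias[..., b, :, :] @ np.swapaxes(Rb, -1, -2)
            r = (Rb @ coms[..., b, :, None])[..., 0]
            cb = p[..., f, :] + r
            wf = w[..., f, :]
            cdot = v[..., f, :] + _cross(wf, r)
            Ltot = Ltot + masses[..., b, None] * _cross(cb, cdot)
            Ltot = Ltot + (Iw @ wf[..., None])[..., 0]
        return Ltot

    def collision_points(self, q, lengths=None):
        """World centres of the collision spheres.

        Returns ``(torso_centres, tail_centres)`` with shapes
        (..., n_torso, 3) and (..., n + 1, 3): the torso row of spheres,
        then one sphere per tail joint connection plus the tail tip.
        Lengths propagate so the tip centre is differentiable in L.
        """
        if lengths is None:
            lengths = self._default_lengths
        lengths = np.asarray(lengths)
        R, p, _ = self._fk(q, lengths)
        params = self.model.params
        half = self.model.torso.length / 2.0
        nt = params.torso_sphere_count
        if nt == 1:
            ys = np.array([0.0])
        else:
            ys = np.linspace(-0.75 * half, 0.75 * half, nt)
        Rt = R[..., self._torso_frame, :, :]
        batch = Rt.shape[:-2]
        torso = np.zeros(batch + (nt, 3), dtype=R.dtype)
        for k, y in enumerate(ys):
            torso[..., k, :] = y * Rt[..., :, 1]  # base pinned at the origin
        tail = np.zeros(batch + (self.n + 1, 3), dtype=R.dtype)
        for i in range(self.n):
            tail[..., i, :] = p[..., 3 + 2 * i, :]
        tail[..., self.n, :] = self.tip_position(q, lengths)
        return torso, tail

    def kinetic_energy(self, q, qdot, lengths=None):
        M = self.mass_matrix(q, lengths)
        qd = np.asarray(qdot)
        return 0.5 * np.einsum("...i,...ij,...j->...", qd, M, qd)

    # -- time integration -------------------------------------------------

    def integrate(
        self,
        x0: np.ndarray,
        control: Callable[[float], np.ndarray],
        t0: float,
        tf: float,
        t_eval: Sequence[float] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        lengths=None,
    ):
        """Forward-simulate ẋ = f(x, u(t)) with an adaptive RK integrator.

        ``control`` maps time to the tail torque vector.  Returns the
        scipy ``OdeResult`` (fields ``t``, ``y`` with states in columns).
        """
        def rhs(t, x):
            return self.f(x, np.asarray(control(t)), lengths)

        sol = solve_ivp(
            rhs, (t0, tf), np.asarray(x0, dtype=float),
            method="RK45", t_eval=t_eval, rtol=rtol, atol=atol,
            dense_output=t_eval is None,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]}: {sol.message}")
        return sol


# -- module-level functional wrappers ------------------------------------

def mass_matrix(model: ModelSpec, q) -> np.ndarray:
    return ChainDynamics(model).mass_matrix(q)


def bias_forces(model: ModelSpec, q, qdot) -> np.ndarray:
    return ChainDynamics(model).bias_forces(q, qdot)


def forward_dynamics(model: ModelSpec, q, qdot, u) -> np.ndarray:
    return ChainDynamics(model).forward_dynamics(q, qdot, u)


def tip_velocity(model: ModelSpec, q, qdot):
    return ChainDynamics(model).tip_velocity(q, qdot)


def angular_momentum(model: ModelSpec, q, qdot) -> np.ndarray:
    return ChainDynamics(model).angular_momentum(q, qdot)


def kinetic_energy(model: ModelSpec, q, qdot) -> np.ndarray:
    return ChainDynamics(model).kinetic_energy(q, qdot)


def integrate(model: ModelSpec, x0, control, t0, tf, **kw):
    return ChainDynamics(model).integrate(x0, control, t0, tf, **kw)
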