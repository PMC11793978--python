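"""Hermite–Simpson direct collocation for the torso-tracking problem.

The continuous problem — make the torso orientation follow a target
Theta(t) using only tail torques, subject to joint position/velocity
boxes, torque boxes, torque-rate bounds, a shared total control-effort
cap u'u <= E and sphere-pair self-collision constraints — is transcribed
into a sparse nonlinear program:

* decision variables are the states x_k = (q_k, qdot_k) and controls
  u_k at the N+1 knots of a uniform grid (plus, optionally, the
  vertebral lengths in the co-design variant);
* the control is piecewise linear (midpoint control = knot average),
  states are the Hermite cubic implied by knot states and dynamics;
* dynamics enter as N * 2nq Hermite–Simpson defect equalities;
* the objective is the Simpson-rule quadrature of the squared tracking
  error ||C x(t) - Theta(t)||^2, evaluated at knots and Hermite
  midpoints.

All constraint Jacobians and the objective gradient are exact
(complex-step dynamics derivatives assembled into sparse matrices); the
NLP is solved with scipy's large-scale interior trust-region method
(``trust-constr``) from five initial guesses, keeping the best feasible
solution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy.optimize import (
    BFGS,
    LinearConstraint,
    NonlinearConstraint,
    minimize,
)

from .dynamics import ChainDynamics
from .model import ModelSpec
from .targets import FourierTargetTrajectory

__all__ = [
    "TimeGrid",
    "ConstraintBounds",
    "CollocationProblem",
    "SolveResult",
    "OptimizationFailure",
    "transcribe",
    "solve",
    "multistart",
    "validate",
    "FAST_GRID",
    "REFERENCE_GRID",
]


class OptimizationFailure(RuntimeError):
    """All multistart attempts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Uniform collocation grid; dt must divide the horizon."""

    t0: float = 0.0
    tf: float = 0.5
    dt: float = 0.02

    def __post_init__(self):
        n = (self.tf - self.t0) / self.dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(f"dt={self.dt} does not divide horizon "
                             f"[{self.t0}, {self.tf}]")

    @property
    def n_intervals(self) -> int:
        return int(round((self.tf - self.t0) / self.dt))

    @property
    def knots(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_intervals + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.knots[:-1] + 0.5 * self.dt


#: desk-scale grid used by the test-suite and reproduction experiments
FAST_GRID = TimeGrid(dt=0.02)
#: the full-scale reference grid (125 intervals over 0.5 s)
REFERENCE_GRID = TimeGrid(dt=0.004)


@dataclasses.dataclass(frozen=True)
class ConstraintBounds:
    """Box, rate and effort bounds of the tracking problem."""

    state_lb: np.ndarray
    state_ub: np.ndarray
    input_lb: np.ndarray
    input_ub: np.ndarray
    rate_lb: np.ndarray
    rate_ub: np.ndarray
    effort_cap: float

    @classmethod
    def from_model(cls, model: ModelSpec) -> "ConstraintBounds":
        p = model.params
        nq, nu = model.nq, model.nu
        lim = model.joint_limits
        qlb = np.concatenate([
            np.full(3, -p.torso_angle_limit),
            np.full(nu, lim.position_range[0]),
        ])
        qub = np.concatenate([
            np.full(3, p.torso_angle_limit),
            np.full(nu, lim.position_range[1]),
        ])
        vlb = np.concatenate([
            np.full(3, -p.torso_rate_limit),
            np.full(nu, lim.velocity_range[0]),
        ])
        vub = np.concatenate([
            np.full(3, p.torso_rate_limit),
            np.full(nu, lim.velocity_range[1]),
        ])
        return cls(
            state_lb=np.concatenate([qlb, vlb]),
            state_ub=np.concatenate([qub, vub]),
            input_lb=np.full(nu, lim.torque_range[0]),
            input_ub=np.full(nu, lim.torque_range[1]),
            rate_lb=np.full(nu, -p.torque_rate_limit),
            rate_ub=np.full(nu, p.torque_rate_limit),
            effort_cap=p.effort_cap,
        )


@dataclasses.dataclass
class SolveResult:
    """Optimized trajectory for one (model, target) pair."""

    times: np.ndarray            # (N+1,)
    states: np.ndarray           # (N+1, 2nq)
    controls: np.ndarray         # (N+1, nu)
    cost: float                  # rad^2 s
    solver_status: str           # optimal | acceptable | failed
    init_label: str
    iterations: int
    constraint_violation: float
    lengths: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "times": self.times.tolist(),
            "states": self.states.tolist(),
            "controls": self.controls.tolist(),
            "cost": self.cost,
            "solver_status": self.solver_status,
            "init_label": self.init_label,
            "iterations": self.iterations,
            "constraint_violation": self.constraint_violation,
        }
        if self.lengths is not None:
            d["lengths"] = self.lengths.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SolveResult":
        return cls(
            times=np.array(d["times"]),
            states=np.array(d["states"]),
            controls=np.array(d["controls"]),
            cost=float(d["cost"]),
            solver_status=d["solver_status"],
            init_label=d["init_label"],
            iterations=int(d["iterations"]),
            constraint_violation=float(d["constraint_violation"]),
            lengths=np.array(d["lengths"]) if "lengths" in d else None,
        )


def _block_sparse(blocks: np.ndarray, row0: np.ndarray, cols: np.ndarray,
                  shape: tuple[int, int]) -> sp.csr_matrix:
    """Assemble (N, r, c) dense blocks into one sparse matrix.

    Block k occupies rows ``row0[k] : row0[k]+r`` and the (possibly
    non-contiguous) columns ``cols[k]`` (length c).
    """
    N, r, c = blocks.shape
    rows = (row0[:, None, None] + np.arange(r)[None, :, None])
    rows = np.broadcast_to(rows, (N, r, c)).ravel()
    colidx = np.broadcast_to(cols[:, None, :], (N, r, c)).ravel()
    return sp.coo_matrix((blocks.ravel(), (rows, colidx)), shape=shape).tocsr()


class CollocationProblem:
    """Transcribed NLP for one model and one target trajectory.

    With ``optimize_lengths=True`` the vertebral lengths join the
    decision vector (the co-design problem): dynamics, collision
    geometry, mass and inertia all become functions of L, with exact
    derivatives taken by complex step through the same dynamics code.
    """

    def __init__(
        self,
        model: ModelSpec,
        target: FourierTargetTrajectory,
        grid: TimeGrid | None = None,
        bounds: ConstraintBounds | None = None,
        optimize_lengths: bool = False,
    ):
        self.model = model
        self.target = target
        self.grid = grid or FAST_GRID
        self.bounds = bounds or ConstraintBounds.from_model(model)
        self.dyn = ChainDynamics(model)
        self.optimize_lengths = optimize_lengths
        if abs(self.grid.t0 - target.t0) > 1e-12 or abs(self.grid.tf - target.tf) > 1e-12:
            raise ValueError("grid horizon must match target horizon")

        self.nq = model.nq
        self.nx = 2 * model.nq
        self.nu = model.nu
        self.N = self.grid.n_intervals
        self.nL = model.n_vertebrae if optimize_lengths else 0
        if optimize_lengths:
            hlb = model.params.min_vertebra_length
            gamma = model.params.tail_total_length
            if model.n_vertebrae * hlb > gamma + 1e-12:
                raise ValueError(
                    f"{model.n_vertebrae} vertebrae with minimum length "
                    f"{hlb} m cannot fit in total length {gamma} m"
                )
        # decision vector layout: [X (N+1)*nx | U (N+1)*nu | L (nL)]
        self.n_knots = self.N + 1
        self._x_off = 0
        self._u_off = self.n_knots * self.nx
        self._l_off = self._u_off + self.n_knots * self.nu
        self.n_vars = self._l_off + self.nL

        # selection matrix C extracting the torso orientation from x
        self.C = np.zeros((3, self.nx))
        self.C[:, :3] = np.eye(3)

        tt, _ = target.evaluate(self.grid.knots)
        tm, _ = target.evaluate(self.grid.midpoints)
        self._theta_knots = tt      # (N+1, 3)
        self._theta_mids = tm       # (N, 3)

        # which collision sphere pairs vary with q: the sphere at the
        # tail-base joint is rigidly attached to the torso (its distance
        # to every torso sphere is constant), so it is excluded
        self._n_torso_spheres = model.params.torso_sphere_count
        self._mobile_tail = list(range(1, model.n_vertebrae + 1))
        self.ng = self._n_torso_spheres * len(self._mobile_tail)

        self._cache: dict[bytes, dict] = {}
        self._ro_key = None
        self._ro_X: np.ndarray | None = None
        self._rs_key = None
        self._rs: dict | None = None

    # -- layout helpers ---------------------------------------------------

    def unpack(self, z: np.ndarray):
        X = z[self._x_off:self._u_off].reshape(self.n_knots, self.nx)
        U = z[self._u_off:self._l_off].reshape(self.n_knots, self.nu)
        if self.nL:
            L = z[self._l_off:]
        else:
            L = np.asarray(self.model.tail.lengths, dtype=float)
        return X, U, L

    def pack(self, X, U, L=None) -> np.ndarray:
        parts = [np.asarray(X, dtype=float).ravel(),
                 np.asarray(U, dtype=float).ravel()]
        if self.nL:
            if L is None:
                L = self.model.tail.lengths
            parts.append(np.asarray(L, dtype=float).ravel())
        return np.concatenate(parts)

    # -- cached stage evaluation ------------------------------------------

    def _stage(self, z: np.ndarray) -> dict:
        """f, midpoint states and all dynamics Jacobians at one z."""
        key = np.asarray(z, dtype=float).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        X, U, L = self.unpack(np.asarray(z, dtype=float))
        dt = self.grid.dt
        fK = self.dyn.f(X, U, L)                       # (N+1, nx)
        Xm = 0.5 * (X[:-1] + X[1:]) + dt / 8.0 * (fK[:-1] - fK[1:])
        Um = 0.5 * (U[:-1] + U[1:])
        fM = self.dyn.f(Xm, Um, L)                     # (N, nx)
        if self.nL:
            AK, BK, GK = self.dyn.f_jac(X, U, L, with_lengths=True)
            AM, BM, GM = self.dyn.f_jac(Xm, Um, L, with_lengths=True)
        else:
            AK, BK = self.dyn.f_jac(X, U, L)
            AM, BM = self.dyn.f_jac(Xm, Um, L)
            GK = GM = None
        out = dict(X=X, U=U, L=L, fK=fK, Xm=Xm, Um=Um, fM=fM,
                   AK=AK, BK=BK, AM=AM, BM=BM, GK=GK, GM=GM)
        if len(self._cache) > 2:
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = out
        return out

    def _xm_partials(self, s):
        """Jacobian blocks of the Hermite midpoint state."""
        dt = self.grid.dt
        I = np.eye(self.nx)
        dXm_dxk = 0.5 * I + dt / 8.0 * s["AK"][:-1]
        dXm_dxk1 = 0.5 * I - dt / 8.0 * s["AK"][1:]
        dXm_duk = dt / 8.0 * s["BK"][:-1]
        dXm_duk1 = -dt / 8.0 * s["BK"][1:]
        out = [dXm_dxk, dXm_dxk1, dXm_duk, dXm_duk1]
        if self.nL:
            out.append(dt / 8.0 * (s["GK"][:-1] - s["GK"][1:]))
        return out

    # -- objective --------------------------------------------------------

    def objective(self, z: np.ndarray) -> float:
        s = self._stage(z)
        eK = s["X"][:, :3] - self._theta_knots
        eM = s["Xm"][:, :3] - self._theta_mids
        ek2 = np.sum(eK**2, axis=1)
        em2 = np.sum(eM**2, axis=1)
        return float(self.grid.dt / 6.0 *
                     np.sum(ek2[:-1] + 4.0 * em2 + ek2[1:]))

    def objective_grad(self, z: np.ndarray) -> np.ndarray:
        s = self._stage(z)
        dt = self.grid.dt
        g = np.zeros(self.n_vars)
        eK = s["X"][:, :3] - self._theta_knots
        eM = s["Xm"][:, :3] - self._theta_mids
        # knot terms: interior knots appear in two intervals
        wk = np.ones(self.n_knots)
        wk[1:-1] = 2.0
        gX = g[self._x_off:self._u_off].reshape(self.n_knots, self.nx)
        gX[:, :3] += dt / 6.0 * wk[:, None] * 2.0 * eK
        # midpoint terms, chained through the Hermite midpoint state
        w = dt / 6.0 * 4.0 * 2.0
        parts = self._xm_partials(s)
        dXm_dxk, dXm_dxk1, dXm_duk, dXm_duk1 = parts[:4]
        eMfull = np.zeros((self.N, self.nx))
        eMfull[:, :3] = eM
        gX[:-1] += w * np.einsum("ki,kij->kj", eMfull, dXm_dxk)
        gX[1:] += w * np.einsum("ki,kij->kj", eMfull, dXm_dxk1)
        gU = g[self._u_off:self._l_off].reshape(self.n_knots, self.nu)
        gU[:-1] += w * np.einsum("ki,kij->kj", eMfull, dXm_duk)
        gU[1:] += w * np.einsum("ki,kij->kj", eMfull, dXm_duk1)
        if self.nL:
            g[self._l_off:] += w * np.einsum(
                "ki,kij->j", eMfull, parts[4]
            )
        return g

    # -- defect constraints ----------------------------------------------

    def defects(self, z: np.ndarray) -> np.ndarray:
        s = self._stage(z)
        dt = self.grid.dt
        X, fK, fM = s["X"], s["fK"], s["fM"]
        d = X[1:] - X[:-1] - dt / 6.0 * (fK[:-1] + 4.0 * fM + fK[1:])
        return d.ravel()

    def _defect_blocks(self, z: np.ndarray):
        """Per-interval dense Jacobian blocks of the defects."""
        s = self._stage(z)
        dt = self.grid.dt
        I = np.eye(self.nx)
        parts = self._xm_partials(s)
        dXm_dxk, dXm_dxk1, dXm_duk, dXm_duk1 = parts[:4]
        AM, BM = s["AM"], s["BM"]
        Dxk = -I - dt / 6.0 * (s["AK"][:-1] + 4.0 * AM @ dXm_dxk)
        Dxk1 = I - dt / 6.0 * (s["AK"][1:] + 4.0 * AM @ dXm_dxk1)
        Duk = -dt / 6.0 * (s["BK"][:-1] + 4.0 * (AM @ dXm_duk + 0.5 * BM))
        Duk1 = -dt / 6.0 * (s["BK"][1:] + 4.0 * (AM @ dXm_duk1 + 0.5 * BM))
        DL = None
        if self.nL:
            DL = -dt / 6.0 * (
                s["GK"][:-1] + 4.0 * (np.einsum("kij,kjl->kil", AM, parts[4])
                                      + s["GM"]) + s["GK"][1:]
            )
        return Dxk, Dxk1, Duk, Duk1, DL

    def defects_jac(self, z: np.ndarray) -> sp.csr_matrix:
        Dxk, Dxk1, Duk, Duk1, DL = self._defect_blocks(z)
        N, nx, nu = self.N, self.nx, self.nu
        row0 = nx * np.arange(N)
        k = np.arange(N)
        shape = (N * nx, self.n_vars)
        xcols = self._x_off + nx * k[:, None] + np.arange(nx)[None, :]
        ucols = self._u_off + nu * k[:, None] + np.arange(nu)[None, :]
        J = (
            _block_sparse(Dxk, row0, xcols, shape)
            + _block_sparse(Dxk1, row0, xcols + nx, shape)
            + _block_sparse(Duk, row0, ucols, shape)
            + _block_sparse(Duk1, row0, ucols + nu, shape)
        )
        if self.nL:
            lcols = np.broadcast_to(
                self._l_off + np.arange(self.nL)[None, :], (N, self.nL)
            )
            J = J + _block_sparse(DL, row0, lcols, shape)
        return J

    # -- effort cap (quadratic, knots and midpoints) ----------------------

    def effort(self, z: np.ndarray) -> np.ndarray:
        X, U, L = self.unpack(np.asarray(z, dtype=float))
        Um = 0.5 * (U[:-1] + U[1:])
        return np.concatenate([np.sum(U**2, axis=1), np.sum(Um**2, axis=1)])

    def effort_jac(self, z: np.ndarray) -> sp.csr_matrix:
        X, U, L = self.unpack(np.asarray(z, dtype=float))
        Um = 0.5 * (U[:-1] + U[1:])
        n_knots, nu, N = self.n_knots, self.nu, self.N
        shape = (n_knots + N, self.n_vars)
        k = np.arange(n_knots)
        ucols = self._u_off + nu * k[:, None] + np.arange(nu)[None, :]
        Jk = _block_sparse((2.0 * U)[:, None, :], k, ucols, shape)
        km = np.arange(N)
        row0 = n_knots + km
        Jm = _block_sparse(Um[:, None, :], row0, ucols[:-1], shape)
        Jm = Jm + _block_sparse(Um[:, None, :], row0, ucols[1:], shape)
        return (Jk + Jm).tocsr()

    # -- collision constraints (knots) -------------------------------------

    def _collision_all(self, Q, L):
        """g values for all knots; complex-step safe."""
        torso, tail = self.dyn.collision_points(Q, L)
        p = self.model.params
        rt, rl = p.torso_sphere_radius, p.tail_sphere_radius
        tail = tail[..., self._mobile_tail, :]
        d = torso[..., :, None, :] - tail[..., None, :, :]
        dist = np.sqrt(np.sum(d * d, axis=-1))
        g = (rt + rl) - dist
        return g.reshape(g.shape[:-2] + (self.ng,))

    def collision(self, z: np.ndarray) -> np.ndarray:
        X, U, L = self.unpack(np.asarray(z, dtype=float))
        return self._collision_all(X[:, :self.nq], L).ravel()

    def collision_jac(self, z: np.ndarray) -> sp.csr_matrix:
        X, U, L = self.unpack(np.asarray(z, dtype=float))
        Q = X[:, :self.nq]
        h = 1e-100
        D = self.nq + self.nL
        Qc = np.repeat(Q[:, None, :].astype(complex), D, axis=1)
        Lc = np.broadcast_to(L, (self.n_knots, self.model.n_vertebrae))
        Lc = np.repeat(Lc[:, None, :].astype(complex), D, axis=1)
        idx = np.arange(self.nq)
        Qc[:, idx, idx] += 1j * h
        if self.nL:
            idx = np.arange(self.nL)
            Qc_idx = self.nq + idx
            Lc[:, Qc_idx, idx] += 1j * h
        G = self._collision_all(Qc, Lc).imag / h   # (n_knots, D, ng)
        G = np.swapaxes(G, 1, 2)                   # (n_knots, ng, D)
        n_knots, ng, nx = self.n_knots, self.ng, self.nx
        shape = (n_knots * ng, self.n_vars)
        k = np.arange(n_knots)
        row0 = ng * k
        qcols = self._x_off + nx * k[:, None] + np.arange(self.nq)[None, :]
        J = _block_sparse(G[:, :, :self.nq], row0, qcols, shape)
        if self.nL:
            lcols = np.broadcast_to(
                self._l_off + np.arange(self.nL)[None, :], (n_knots, self.nL)
            )
            J = J + _block_sparse(G[:, :, self.nq:], row0, lcols, shape)
        return J

    # -- linear constraints and variable bounds -----------------------------

    def rate_constraint(self) -> LinearConstraint:
        """Bounds on (u_{k+1} - u_k) / dt."""
        N, nu = self.N, self.nu
        rows = np.arange(N * nu)
        data = np.concatenate([-np.ones(N * nu), np.ones(N * nu)])
        cols_lo = self._u_off + np.arange(N * nu)
        cols_hi = cols_lo + nu
        A = sp.coo_matrix(
            (data / self.grid.dt,
             (np.concatenate([rows, rows]),
              np.concatenate([cols_lo, cols_hi]))),
            shape=(N * nu, self.n_vars),
        ).tocsr()
        lb = np.tile(self.bounds.rate_lb, N)
        ub = np.tile(self.bounds.rate_ub, N)
        return LinearConstraint(A, lb, ub)

    def length_sum_constraint(self) -> LinearConstraint | None:
        if not self.nL:
            return None
        A = sp.coo_matrix(
            (np.ones(self.nL),
             (np.zeros(self.nL, dtype=int),
              self._l_off + np.arange(self.nL))),
            shape=(1, self.n_vars),
        ).tocsr()
        gamma = self.model.params.tail_total_length
        return LinearConstraint(A, gamma, gamma)

    def variable_bounds(self):
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)
        lb[self._x_off:self._u_off] = np.tile(self.bounds.state_lb, self.n_knots)
        ub[self._x_off:self._u_off] = np.tile(self.bounds.state_ub, self.n_knots)
        lb[self._u_off:self._l_off] = np.tile(self.bounds.input_lb, self.n_knots)
        ub[self._u_off:self._l_off] = np.tile(self.bounds.input_ub, self.n_knots)
        if self.nL:
            lb[self._l_off:] = self.model.params.min_vertebra_length
            ub[self._l_off:] = self.model.params.tail_total_length
        # the system starts at rest at the (zero) target orientation
        lb[self._x_off:self._x_off + self.nx] = 0.0
        ub[self._x_off:self._x_off + self.nx] = 0.0
        return lb, ub

    # -- initial guesses ----------------------------------------------------

    def initial_guesses(self, seed: int = 0) -> list[tuple[str, np.ndarray]]:
        """The five multistart initializations.

        (1) all zeros; (2) torso orientation linearly interpolating from
        the initial to the final target orientation, everything else
        zero; (3-5) uniform random within the box bounds.  Lengths, when
        present, always start uniform.
        """
        n_knots, nx, nu = self.n_knots, self.nx, self.nu
        uniform_L = np.full(
            self.model.n_vertebrae,
            self.model.params.tail_total_length / self.model.n_vertebrae,
        ) if self.nL else None
        guesses = []
        X = np.zeros((n_knots, nx))
        U = np.zeros((n_knots, nu))
        guesses.append(("zeros", self.pack(X, U, uniform_L)))
        X2 = X.copy()
        tau = (self.grid.knots - self.grid.t0) / (self.grid.tf - self.grid.t0)
        theta_f, _ = self.target.evaluate(np.array(self.grid.tf))
        X2[:, :3] = tau[:, None] * theta_f[None, :]
        guesses.append(("linear", self.pack(X2, U, uniform_L)))
        rng = np.random.default_rng(seed)
        lb, ub = self.variable_bounds()
        for i in range(3):
            z = rng.uniform(lb, ub)
            if self.nL:
                z[self._l_off:] = uniform_L
            z[:nx] = 0.0  # keep the fixed initial state
            guesses.append((f"random_{i + 1}", z))
        return guesses

    # -- solving -------------------------------------------------------------

    def constraints(self):
        cons = [
            NonlinearConstraint(
                self.defects, 0.0, 0.0, jac=self.defects_jac, hess=BFGS()
            ),
            NonlinearConstraint(
                self.effort, -np.inf, self.bounds.effort_cap,
                jac=self.effort_jac, hess=BFGS(),
            ),
            NonlinearConstraint(
                self.collision, -np.inf, 0.0,
                jac=self.collision_jac, hess=BFGS(),
            ),
            self.rate_constraint(),
        ]
        lsc = self.length_sum_constraint()
        if lsc is not None:
            cons.append(lsc)
        return cons

    def constraint_violation(self, z: np.ndarray) -> float:
        """Worst violation of every path constraint, re-checked directly.

        Each constraint family is measured on its natural scale so the
        number is comparable with the (scaled) solver tolerance: defects
        and boxes in their own units (rad, rad/s, Nm, m), the effort cap
        relative to E, torque rates relative to the rate limit.
        """
        v = [np.abs(self.defects(z)).max()]
        v.append(max(0.0, (self.effort(z) - self.bounds.effort_cap).max())
                 / self.bounds.effort_cap)
        v.append(max(0.0, self.collision(z).max()))
        X, U, L = self.unpack(z)
        rate = np.diff(U, axis=0) / self.grid.dt
        rs = self.model.params.torque_rate_limit
        v.append(max(0.0, (rate - self.bounds.rate_ub).max(initial=0.0)) / rs)
        v.append(max(0.0, (self.bounds.rate_lb - rate).max(initial=0.0)) / rs)
        lb, ub = self.variable_bounds()
        v.append(max(0.0, (z - ub).max(initial=0.0)))
        v.append(max(0.0, (lb - z).max(initial=0.0)))
        if self.nL:
            v.append(abs(L.sum() - self.model.params.tail_total_length))
        return float(max(v))

    # -- reduced space: states eliminated through the defect system --------

    def _newton_states(self, z: np.ndarray, tol: float = 1e-11,
                       maxiter: int = 12) -> tuple[np.ndarray, float]:
        """Damped global Newton on the defects over the free knot states."""
        z = np.asarray(z, dtype=float).copy()
        nx = self.nx
        free = slice(self._x_off + nx, self._x_off + self.n_knots * nx)
        with np.errstate(all="ignore"):
            res = np.abs(self.defects(z)).max()
            res0 = res
            for it in range(maxiter):
                if res < tol or not np.isfinite(res):
                    break
                if res > max(1e4, 1e3 * res0):  # hopeless; bail out early
                    break
                if it >= 3 and res > 1e6:
                    break
                J = self.defects_jac(z)[:, free].tocsc()
                try:
                    step = sp.linalg.spsolve(J, -self.defects(z))
                except RuntimeError:
                    break
                if not np.all(np.isfinite(step)):
                    break
                alpha = 1.0
                for _ in range(8):
                    z_try = z.copy()
                    z_try[free] += alpha * step
                    res_try = np.abs(self.defects(z_try)).max()
                    if res_try < res:
                        z, res = z_try, res_try
                        break
                    alpha *= 0.5
                else:
                    break
        return z, res

    def _euler_predictor(self, U: np.ndarray, L) -> np.ndarray:
        X = np.zeros((self.n_knots, self.nx))
        dt = self.grid.dt
        for k in range(self.N):
            X[k + 1] = X[k] + dt * self.dyn.f(X[k], U[k], L)
        return X

    def rollout(self, U: np.ndarray, L=None, X_guess: np.ndarray | None = None,
                tol: float = 1e-10) -> np.ndarray:
        """States satisfying every Hermite–Simpson defect for given controls.

        The defect system squares off against the free knot states, so
        it defines an implicit integrator; it is solved by damped Newton
        warm-started from ``X_guess`` (or the previous rollout, or an
        explicit Euler prediction).
        """
        U = np.asarray(U, dtype=float)
        if L is None:
            L = np.asarray(self.model.tail.lengths, dtype=float)
        L = np.asarray(L, dtype=float)
        key = (U.tobytes(), L.tobytes())
        if self._ro_key == key:
            return self._ro_X
        ws = X_guess if X_guess is not None else self._ro_X
        tried_predictor = ws is None
        if ws is None:
            with np.errstate(all="ignore"):
                ws = self._euler_predictor(U, L)
        z, res = self._newton_states(self.pack(ws, U, L))
        # retry from a fresh prediction only when the warm start was
        # plausibly the problem (moderate residual); a blown-up residual
        # means the controls themselves are pathological
        if tol < res < 1e3 and not tried_predictor:
            with np.errstate(all="ignore"):
                ws = self._euler_predictor(U, L)
            z, res = self._newton_states(self.pack(ws, U, L))
        if res > tol or not np.isfinite(res):
            raise OptimizationFailure(
                f"implicit rollout failed to converge (residual {res:.2e})"
            )
        X, _, _ = self.unpack(z)
        self._ro_key, self._ro_X = key, X.copy()
        return X

    def _reduced_m(self) -> int:
        return self.n_knots * self.nu + self.nL

    def _split_v(self, v: np.ndarray):
        U = v[: self.n_knots * self.nu].reshape(self.n_knots, self.nu)
        L = v[self.n_knots * self.nu:] if self.nL else np.asarray(
            self.model.tail.lengths, dtype=float
        )
        return U, L

    def _reduced_stage(self, v: np.ndarray) -> dict:
        """Rollout, full-space point and state sensitivities dX/d(U, L)."""
        v = np.asarray(v, dtype=float)
        key = v.tobytes()
        if self._rs_key == key:
            return self._rs
        U, L = self._split_v(v)
        try:
            X = self.rollout(U, L)
        except OptimizationFailure:
            # controls for which the implicit step has no reachable
            # solution (line-search excursions): poison this point so the
            # SQP merit function rejects it
            self._rs_key, self._rs = key, dict(failed=True)
            return self._rs
        z = self.pack(X, U, L)
        with np.errstate(all="ignore"):
            Dxk, Dxk1, Duk, Duk1, DL = self._defect_blocks(z)
        m = self._reduced_m()
        nu, nx = self.nu, self.nx
        G = np.zeros((self.n_knots, nx, m))
        for k in range(self.N):
            rhs = Dxk[k] @ G[k]
            rhs[:, k * nu:(k + 1) * nu] += Duk[k]
            rhs[:, (k + 1) * nu:(k + 2) * nu] += Duk1[k]
            if self.nL:
                rhs[:, self.n_knots * nu:] += DL[k]
            G[k + 1] = -np.linalg.solve(Dxk1[k], rhs)
        Gbig = G.reshape(self.n_knots * nx, m)
        self._rs_key, self._rs = key, dict(
            z=z, X=X, U=U, L=L, Gbig=Gbig, failed=False
        )
        return self._rs

    def _reduce_jac(self, J, Gbig) -> np.ndarray:
        """Chain a full-space Jacobian through the state sensitivities."""
        J = sp.csr_matrix(J)
        xdim = self.n_knots * self.nx
        return np.asarray((J[:, :xdim] @ Gbig) + J[:, xdim:].toarray())

    _FAIL_COST = 1e4

    def _n_reduced_ineq(self) -> int:
        return (2 * self.N * self.nx + self.n_knots + self.N
                + self.n_knots * self.ng + 2 * self.N * self.nu)

    def reduced_objective(self, v: np.ndarray) -> float:
        s = self._reduced_stage(v)
        if s["failed"]:
            return self._FAIL_COST
        return self.objective(s["z"])

    def reduced_objective_grad(self, v: np.ndarray) -> np.ndarray:
        s = self._reduced_stage(v)
        if s["failed"]:
            return np.zeros(self._reduced_m())
        g = self.objective_grad(s["z"])
        xdim = self.n_knots * self.nx
        return g[:xdim] @ s["Gbig"] + g[xdim:]

    def _reduced_ineq(self, v: np.ndarray) -> np.ndarray:
        """All path inequalities, oriented as c(v) >= 0."""
        s = self._reduced_stage(v)
        if s["failed"]:
            return np.full(self._n_reduced_ineq(), -self._FAIL_COST)
        X, U = s["X"], s["U"]
        lbx, ubx = self.bounds.state_lb, self.bounds.state_ub
        state_hi = (ubx[None, :] - X[1:]).ravel()
        state_lo = (X[1:] - lbx[None, :]).ravel()
        eff = self.bounds.effort_cap - self.effort(s["z"])
        col = -self.collision(s["z"])
        rate = np.diff(U, axis=0).ravel() / self.grid.dt
        rate_hi = np.tile(self.bounds.rate_ub, self.N) - rate
        rate_lo = rate - np.tile(self.bounds.rate_lb, self.N)
        return np.concatenate([state_hi, state_lo, eff, col, rate_hi, rate_lo])

    def _reduced_ineq_jac(self, v: np.ndarray) -> np.ndarray:
        s = self._reduced_stage(v)
        if s["failed"]:
            return np.zeros((self._n_reduced_ineq(), self._reduced_m()))
        Gbig = s["Gbig"]
        nx, m = self.nx, self._reduced_m()
        Gx = Gbig[nx:]  # rows of X_1..X_N
        effJ = self._reduce_jac(self.effort_jac(s["z"]), Gbig)
        colJ = self._reduce_jac(self.collision_jac(s["z"]), Gbig)
        rc = self.rate_constraint()
        xdim = self.n_knots * self.nx
        rateJ = rc.A.tocsr()[:, xdim:].toarray()
        return np.vstack([-Gx, Gx, -effJ, -colJ, rateJ, -rateJ])

    def solve_reduced(
        self,
        guess: np.ndarray,
        init_label: str = "custom",
        maxiter: int = 250,
        restarts: int = 4,
        ftol: float = 1e-10,
        constr_tol: float = 1e-6,
    ) -> SolveResult:
        """Solve the NLP in the reduced (control) space with restarted SQP.

        The defects are eliminated exactly at every iterate via the
        implicit rollout, so dynamics feasibility is maintained to
        ~1e-10 throughout and only the path inequalities remain.  SQP
        line searches occasionally shoot far from the feasible region,
        so the iteration budget is spent in chunks, each restarted from
        the best feasible iterate seen so far.
        """
        lb, ub = self.variable_bounds()
        z0 = np.clip(np.asarray(guess, dtype=float), lb, ub)
        X0, U0, L0 = self.unpack(z0)
        self._ro_key, self._ro_X = None, X0  # warm start from the guess states
        self._rs_key, self._rs = None, None
        v0 = np.concatenate([U0.ravel(), L0] if self.nL else [U0.ravel()])
        torque = self.model.joint_limits.torque_range[1]
        S = np.concatenate([
            np.full(self.n_knots * self.nu, torque),
            np.full(self.nL, 0.5),
        ]) if self.nL else np.full(self.n_knots * self.nu, torque)
        obj_scale = 100.0
        gamma = self.model.params.tail_total_length
        vlb = np.tile(self.bounds.input_lb, self.n_knots)
        vub = np.tile(self.bounds.input_ub, self.n_knots)
        if self.nL:
            vlb = np.concatenate(
                [vlb, np.full(self.nL, self.model.params.min_vertebra_length)]
            )
            vub = np.concatenate([vub, np.full(self.nL, gamma)])
        cons = [dict(
            type="ineq",
            fun=lambda w: self._reduced_ineq(S * w),
            jac=lambda w: self._reduced_ineq_jac(S * w) * S[None, :],
        )]
        if self.nL:
            A = np.concatenate([np.zeros(self.n_knots * self.nu),
                                np.ones(self.nL)]) * S
            cons.append(dict(type="eq", fun=lambda w: A @ w - gamma,
                             jac=lambda w: A[None, :]))

        # best near-feasible iterate: SQP line searches can leave the
        # final point worse than the best one visited
        best = {"v": None, "cost": np.inf}

        def _track(wk):
            vk = S * wk
            c = self._reduced_ineq(vk)
            if c.min() >= -constr_tol:
                cost = self.reduced_objective(vk)
                if cost < best["cost"]:
                    best["v"], best["cost"] = vk.copy(), cost

        _track(v0 / S)
        nit = 0
        v_start = v0
        chunk = max(20, maxiter // max(restarts, 1))
        with np.errstate(all="ignore"):
            for _ in range(max(restarts, 1)):
                res = minimize(
                    lambda w: obj_scale * self.reduced_objective(S * w),
                    v_start / S,
                    jac=lambda w: obj_scale * S * self.reduced_objective_grad(S * w),
                    method="SLSQP", bounds=list(zip(vlb / S, vub / S)),
                    constraints=cons, callback=_track,
                    options=dict(maxiter=chunk, ftol=ftol),
                )
                _track(res.x)
                nit += res.nit
                if nit >= maxiter or res.status == 0:
                    break
                # continue the SQP path; fall back to the best feasible
                # iterate if the endpoint's rollout collapsed
                if self._reduced_stage(S * res.x)["failed"]:
                    if best["v"] is None:
                        break
                    v_start = best["v"]
                else:
                    v_start = S * res.x
        vf = S * res.x
        sf = self._reduced_stage(vf)
        if sf["failed"] or (
            best["v"] is not None
            and (self._reduced_ineq(vf).min() < -constr_tol
                 or self.reduced_objective(vf) > best["cost"])
        ):
            vf = best["v"] if best["v"] is not None else v0
        s = self._reduced_stage(vf)
        z = s["z"]
        X, U, L = self.unpack(z)
        viol = self.constraint_violation(z)
        if viol <= constr_tol:
            status = "optimal" if res.status == 0 else "acceptable"
        else:
            status = "failed"
        return SolveResult(
            times=self.grid.knots.copy(),
            states=X.copy(),
            controls=U.copy(),
            cost=self.objective(z),
            solver_status=status,
            init_label=init_label,
            iterations=int(nit),
            constraint_violation=viol,
            lengths=L.copy() if self.nL else None,
        )

    def solve_slsqp(
        self,
        guess: np.ndarray,
        init_label: str = "custom",
        maxiter: int = 100,
        constr_tol: float = 1e-6,
        polish: bool = True,
        margin: float = 0.0,
    ) -> SolveResult:
        """Full-space SQP solve (dense Jacobians, scaled variables).

        SQP iterates are not feasible until convergence, so with a tight
        iteration budget the returned point may violate constraints; the
        defects are Newton-polished afterwards, and the caller is
        expected to check ``solver_status`` / use the result as a warm
        discovery step (its role in the co-design pipeline).

        ``margin`` tightens every symmetric bound (state/torque boxes,
        effort cap, rate bounds) by the given relative amount, so that a
        subsequent exact-rollout repair of the returned controls lands
        inside the *true* constraint set despite small state drift.
        """
        lb, ub = self.variable_bounds()
        S, sdefect = self._scales()
        shrink = 1.0 - margin
        E = self.bounds.effort_cap * shrink
        rs = self.model.params.torque_rate_limit
        rc = self.rate_constraint()
        A = rc.A.toarray()
        obj_scale = 100.0
        cons = [
            dict(type="eq",
                 fun=lambda w: sdefect * self.defects(S * w),
                 jac=lambda w: (sdefect[:, None]
                                * self.defects_jac(S * w).toarray()) * S[None, :]),
            dict(type="ineq",
                 fun=lambda w: 1.0 - self.effort(S * w) / E,
                 jac=lambda w: -self.effort_jac(S * w).toarray() * S[None, :] / E),
            dict(type="ineq",
                 fun=lambda w: -self.collision(S * w),
                 jac=lambda w: -self.collision_jac(S * w).toarray() * S[None, :]),
            dict(type="ineq",
                 fun=lambda w: (rc.ub * shrink - A @ (S * w)) / rs,
                 jac=lambda w: -A * S[None, :] / rs),
            dict(type="ineq",
                 fun=lambda w: (A @ (S * w) - rc.lb * shrink) / rs,
                 jac=lambda w: A * S[None, :] / rs),
        ]
        lsc = self.length_sum_constraint()
        if lsc is not None:
            Als = lsc.A.toarray()
            gamma = float(np.atleast_1d(lsc.lb)[0])
            cons.append(dict(
                type="eq", fun=lambda w: Als @ (S * w) - gamma,
                jac=lambda w: Als * S[None, :],
            ))
        # tightened boxes on states and controls (symmetric about zero;
        # the pinned initial state and the length bounds are unaffected)
        lb_t, ub_t = lb.copy(), ub.copy()
        lb_t[:self._l_off] *= shrink
        ub_t[:self._l_off] *= shrink
        z0 = np.clip(np.asarray(guess, dtype=float), lb_t, ub_t)
        iterates: list[np.ndarray] = []
        with np.errstate(all="ignore"):
            res = minimize(
                lambda w: obj_scale * self.objective(S * w), z0 / S,
                jac=lambda w: obj_scale * S * self.objective_grad(S * w),
                method="SLSQP", bounds=list(zip(lb_t / S, ub_t / S)),
                constraints=cons, callback=lambda w: iterates.append(S * w),
                options=dict(maxiter=maxiter, ftol=1e-12),
            )
        iterates.append(S * res.x)

        def _repair(z_raw: np.ndarray, full: bool = False) -> np.ndarray:
            """Restore feasibility: effort rescale, then the best of
            Newton(/TRF) restoration and the exact implicit rollout
            (whose state drift the tightened bounds absorb).  Candidates
            are clipped to the *true* boxes: near-feasible points (the
            warm start and blends toward it) legitimately ride them."""
            z = np.clip(z_raw, lb, ub)
            X, U, L = self.unpack(z)
            over = self.effort(z).max() / E
            if 1.0 < over < 1.05:
                U = U / np.sqrt(over * (1.0 + 1e-12))
                z = self.pack(X, U, L if self.nL else None)
            candidates = [z, self.polish_defects(z, trf_fallback=full)]
            if margin > 0.0:
                try:
                    X1, U1, L1 = self.unpack(z)
                    self._ro_key, self._ro_X = None, X1
                    Xr = self.rollout(U1, L1 if self.nL else None)
                    zr = self.pack(Xr, U1, L1 if self.nL else None)
                    candidates.append(zr)
                    candidates.append(self.polish_defects(zr,
                                                          trf_fallback=full))
                except OptimizationFailure:
                    pass
            return min(candidates, key=self.constraint_violation)

        if polish:
            # SQP iterates are only feasible in the limit; walk backward
            # along the iterate path (dense near the end, then sparser)
            # until one restores to feasibility, and as a last resort
            # blend the best endpoint toward the feasible start — small
            # enough steps along that homotopy always restore
            z = None
            rev = iterates[::-1]
            tail = rev[:4] + rev[4:16:3]
            for z_raw in tail:
                z_try = _repair(z_raw)
                if self.constraint_violation(z_try) <= constr_tol:
                    z = z_try
                    break
                if z is None or (self.constraint_violation(z_try)
                                 < self.constraint_violation(z)):
                    z = z_try
            if self.constraint_violation(z) > constr_tol:
                z_end = rev[0]
                z_orig = np.clip(np.asarray(guess, dtype=float), lb, ub)
                for alpha in (0.7, 0.5, 0.3, 0.15):
                    z_try = _repair((1 - alpha) * z_orig + alpha * z_end)
                    if self.constraint_violation(z_try) <= constr_tol:
                        if self.objective(z_try) < self.objective(z_orig):
                            z = z_try
                        break
            if self.constraint_violation(z) > constr_tol:
                z_full = _repair(rev[0], full=True)
                if (self.constraint_violation(z_full)
                        < self.constraint_violation(z)):
                    z = z_full
        else:
            z = np.clip(S * res.x, lb_t, ub_t)
        X, U, L = self.unpack(z)
        viol = self.constraint_violation(z)
        status = ("optimal" if res.status == 0 else "acceptable") \
            if viol <= constr_tol else "failed"
        return SolveResult(
            times=self.grid.knots.copy(),
            states=X.copy(), controls=U.copy(), cost=self.objective(z),
            solver_status=status, init_label=init_label,
            iterations=int(res.nit), constraint_violation=viol,
            lengths=L.copy() if self.nL else None,
        )

    # typical magnitudes used to condition the NLP: angles ~1 rad,
    # rates ~ the 2 pi rad/s velocity bound, torques ~ the 5 Nm box,
    # lengths ~ 0.5 m; the objective is scaled to order one
    def _scales(self):
        sx = np.concatenate([np.ones(self.nq), np.full(self.nq, 2.0 * np.pi)])
        svar = np.concatenate([
            np.tile(sx, self.n_knots),
            np.full(self.n_knots * self.nu, 5.0),
            np.full(self.nL, 0.5),
        ])
        sdefect = 1.0 / (self.grid.dt * np.tile(sx, self.N))
        return svar, sdefect

    def _scaled_constraints(self, S, sdefect):
        Ssp = sp.diags(S)
        E = self.bounds.effort_cap
        cons = [
            NonlinearConstraint(
                lambda zt: sdefect * self.defects(S * zt), 0.0, 0.0,
                jac=lambda zt: sp.diags(sdefect) @ self.defects_jac(S * zt) @ Ssp,
                hess=BFGS(),
            ),
            NonlinearConstraint(
                lambda zt: self.effort(S * zt) / E, -np.inf, 1.0,
                jac=lambda zt: (self.effort_jac(S * zt) @ Ssp) / E,
                hess=BFGS(),
            ),
            NonlinearConstraint(
                lambda zt: 10.0 * self.collision(S * zt), -np.inf, 0.0,
                jac=lambda zt: 10.0 * (self.collision_jac(S * zt) @ Ssp),
                hess=BFGS(),
            ),
        ]
        rc = self.rate_constraint()
        rs = self.model.params.torque_rate_limit
        cons.append(LinearConstraint(rc.A @ Ssp / rs, rc.lb / rs, rc.ub / rs))
        lsc = self.length_sum_constraint()
        if lsc is not None:
            cons.append(LinearConstraint(lsc.A @ Ssp, lsc.lb, lsc.ub))
        return cons

    def polish_defects(self, z: np.ndarray, tol: float = 1e-10,
                       maxiter: int = 30, trf_fallback: bool = True) -> np.ndarray:
        """Newton restoration of the defect equalities.

        With controls (and lengths) held fixed, the N * 2nq defect
        equations square off against the N * 2nq free knot states
        (x_0 is pinned), so a few sparse Newton steps drive the dynamics
        residual from solver tolerance to near machine precision without
        perceptibly moving the objective.
        """
        z = np.asarray(z, dtype=float).copy()
        nx = self.nx
        lb, ub = self.variable_bounds()
        free = slice(self._x_off + nx, self._x_off + self.n_knots * nx)
        best = z.copy()
        best_res = np.abs(self.defects(z)).max()
        for _ in range(maxiter):
            d = self.defects(z)
            res = np.abs(d).max()
            if res < best_res:
                best, best_res = z.copy(), res
            if res < tol:
                break
            J = self.defects_jac(z)[:, free].tocsc()
            step = sp.linalg.spsolve(J, -d)
            z[free] += step
            # projected Newton: stay inside the state boxes
            z = np.clip(z, lb, ub)
        if np.abs(self.defects(z)).max() > best_res:
            z = best
        res = np.abs(self.defects(z)).max()
        if trf_fallback and res > max(tol, 1e-9):
            # active state boxes can stall the projected Newton; finish
            # with bounded least squares on the free states
            z = self._restore_defects_trf(z)
        return z

    def _restore_defects_trf(self, z: np.ndarray) -> np.ndarray:
        """Bounded least-squares restoration of the defects."""
        from scipy.optimize import least_squares

        z = np.asarray(z, dtype=float).copy()
        nx = self.nx
        lb, ub = self.variable_bounds()
        free = slice(self._x_off + nx, self._x_off + self.n_knots * nx)

        def resid(xf):
            zz = z.copy()
            zz[free] = xf
            return self.defects(zz)

        def jac(xf):
            zz = z.copy()
            zz[free] = xf
            return self.defects_jac(zz)[:, free]

        x0 = np.clip(z[free], lb[free] + 1e-12, ub[free] - 1e-12)
        with np.errstate(all="ignore"):
            sol = least_squares(
                resid, x0, jac=jac, bounds=(lb[free], ub[free]),
                method="trf", tr_solver="lsmr", max_nfev=100,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        z_new = z.copy()
        z_new[free] = sol.x
        if np.abs(self.defects(z_new)).max() < np.abs(self.defects(z)).max():
            return z_new
        return z

    def solve(
        self,
        guess: np.ndarray,
        init_label: str = "custom",
        method: str = "reduced",
        maxiter: int | None = None,
        restarts: int = 4,
        gtol: float = 1e-8,
        xtol: float = 1e-12,
        constr_tol: float = 1e-6,
        polish: bool = True,
        verbose: int = 0,
    ) -> SolveResult:
        """Solve from one initial guess.

        ``method="reduced"`` (default) eliminates the states through the
        defect system and runs SQP over controls (and lengths);
        ``method="trust-constr"`` solves the full-space NLP with the
        large-scale interior trust-region solver.
        """
        if method == "reduced":
            return self.solve_reduced(
                guess, init_label=init_label,
                maxiter=250 if maxiter is None else maxiter,
                restarts=restarts, constr_tol=constr_tol,
            )
        if method == "slsqp":
            return self.solve_slsqp(
                guess, init_label=init_label,
                maxiter=100 if maxiter is None else maxiter,
                constr_tol=constr_tol, polish=polish,
            )
        if method != "trust-constr":
            raise ValueError(f"unknown solve method {method!r}")
        if maxiter is None:
            maxiter = 1000
        lb, ub = self.variable_bounds()
        S, sdefect = self._scales()
        obj_scale = 100.0
        z0 = np.clip(np.asarray(guess, dtype=float), lb, ub)
        res = minimize(
            lambda zt: obj_scale * self.objective(S * zt),
            z0 / S,
            jac=lambda zt: obj_scale * S * self.objective_grad(S * zt),
            hess=BFGS(),
            method="trust-constr",
            bounds=list(zip(lb / S, ub / S)),
            constraints=self._scaled_constraints(S, sdefect),
            options=dict(maxiter=maxiter, gtol=gtol, xtol=xtol,
                         verbose=verbose),
        )
        z = S * res.x
        if polish:
            zp = self.polish_defects(z)
            if self.constraint_violation(zp) <= self.constraint_violation(z):
                z = zp
        X, U, L = self.unpack(z)
        viol = self.constraint_violation(z)
        if viol <= constr_tol:
            status = "optimal" if res.status in (1, 2) else "acceptable"
        else:
            status = "failed"
        return SolveResult(
            times=self.grid.knots.copy(),
            states=X.copy(),
            controls=U.copy(),
            cost=self.objective(z),
            solver_status=status,
            init_label=init_label,
            iterations=int(res.niter),
            constraint_violation=viol,
            lengths=L.copy() if self.nL else None,
        )

    def multistart(self, seed: int = 0, n_starts: int = 5,
                   **solve_kw) -> SolveResult:
        """Solve from up to five labelled guesses; keep the best feasible."""
        results = []
        for label, z0 in self.initial_guesses(seed)[:n_starts]:
            try:
                results.append(self.solve(z0, init_label=label, **solve_kw))
            except Exception as exc:  # pragma: no cover - solver crash path
                results.append(("error", label, repr(exc)))
        ok = [r for r in results if isinstance(r, SolveResult)
              and r.solver_status != "failed"]
        if not ok:
            raise OptimizationFailure(
                "all multistart attempts failed", diagnostics=results
            )
        return min(ok, key=lambda r: r.cost)

    # -- validation -----------------------------------------------------------

    def control_interpolant(self, result: SolveResult):
        """Piecewise-linear control u(t) consistent with the transcription."""
        times, controls = result.times, result.controls

        def u_of_t(t: float) -> np.ndarray:
            return np.array(
                [np.interp(t, times, controls[:, j])
                 for j in range(controls.shape[1])]
            )

        return u_of_t

    def validate(self, result: SolveResult, rtol: float = 1e-8,
                 atol: float = 1e-10) -> float:
        """Max deviation between forward simulation and the NLP states.

        Integrates the dynamics under the solution's control interpolant
        from x(t0) with an adaptive RK scheme and returns
        max_k ||x_sim(t_k) - x_opt(t_k)||_inf (rad, rad/s).
        """
        u_of_t = self.control_interpolant(result)
        L = result.lengths
        sol = self.dyn.integrate(
            result.states[0], u_of_t, self.grid.t0, self.grid.tf,
            t_eval=result.times, rtol=rtol, atol=atol, lengths=L,
        )
        return float(np.max(np.abs(sol.y.T - result.states)))


# -- module-level wrappers ---------------------------------------------------

def transcribe(
    model: ModelSpec,
    target: FourierTargetTrajectory,
    grid: TimeGrid | None = None,
    bounds: ConstraintBounds | None = None,
) -> CollocationProblem:
    return CollocationProblem(model, target, grid=grid, bounds=bounds)


def solve(problem: CollocationProblem, guess, **kw) -> SolveResult:
    return problem.solve(guess, **kw)


def multistart(problem: CollocationProblem, seed: int = 0, **kw) -> SolveResult:
    return problem.multistart(seed=seed, **kw)


def validate(problem: CollocationProblem, result: SolveResult, **kw) -> float:
    return problem.validate(result, **kw)
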