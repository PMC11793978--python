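"""Morphology co-design: vertebral lengths as decision variables.

The tracking problem is extended with the vertebral lengths L = {l_i}:
dynamics, collision geometry, mass and inertia all become functions of
L (uniform density: mass and inertia are recomputed from each length
inside the NLP), subject to a fixed total length sum(l_i) = Gamma and a
positive lower bound l_i >= H_lb = 0.2 m that keeps vertebrae long
enough for the sphere-based collision model to remain valid without
extra tail–tail constraints.

Solution strategy: the joint (states, controls, lengths) program is
non-convex and unreliable to solve cold at desk scale, so
``solve_codesign`` starts from the uniform-length optimum (which is
feasible for the co-design problem, so the returned cost can never
exceed it) and refines it in two stages: a warm joint SQP over states,
controls and lengths (run against margin-tightened bounds so its
result can be restored to strict feasibility), then a small SQP over
the lengths alone with the controls frozen.  See ``solve_codesign``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from .collocation import (
    CollocationProblem,
    ConstraintBounds,
    SolveResult,
    TimeGrid,
)
from .model import build_uniform_model
from .params import DEFAULT_PARAMS, TableParams
from .targets import FourierTargetTrajectory

__all__ = [
    "CodesignProblem",
    "CodesignResult",
    "transcribe_codesign",
    "length_step",
    "solve_codesign",
]

#: the co-design problem is a CollocationProblem with length variables
CodesignProblem = CollocationProblem

#: result alias: a SolveResult whose ``lengths`` field is populated
CodesignResult = SolveResult


def transcribe_codesign(
    n_vertebrae: int,
    target: FourierTargetTrajectory,
    grid: TimeGrid | None = None,
    bounds: ConstraintBounds | None = None,
    params: TableParams = DEFAULT_PARAMS,
) -> CodesignProblem:
    """Co-design NLP for an ``n_vertebrae`` tail (lengths start uniform).

    Raises if ``n_vertebrae * H_lb`` exceeds the total tail length (the
    length constraints would be infeasible by construction).
    """
    model = build_uniform_model(n_vertebrae, params)
    return CollocationProblem(
        model, target, grid=grid, bounds=bounds, optimize_lengths=True
    )


def length_step(
    problem: CodesignProblem,
    states: np.ndarray,
    controls: np.ndarray,
    lengths: np.ndarray,
    maxiter: int = 60,
    constr_tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Optimize the vertebral lengths with the controls frozen.

    States follow the controls and lengths through the implicit
    Hermite–Simpson rollout, so only the few length variables remain —
    a small, well-conditioned SQP.  Returns the best feasible lengths
    and their cost; never worse than the starting point.
    """
    prob = problem
    if not prob.nL:
        raise ValueError("problem was not transcribed with length variables")
    prob._ro_key, prob._ro_X = None, np.asarray(states, dtype=float)
    prob._rs_key = None
    n_u = prob.n_knots * prob.nu
    u_fixed = np.asarray(controls, dtype=float).ravel()
    gamma = prob.model.params.tail_total_length
    hlb = prob.model.params.min_vertebra_length

    def full_v(L):
        return np.concatenate([u_fixed, L])

    def fun(L):
        return prob.reduced_objective(full_v(L))

    def grad(L):
        return prob.reduced_objective_grad(full_v(L))[n_u:]

    def ineq(L):
        return prob._reduced_ineq(full_v(L))

    def ineq_jac(L):
        return prob._reduced_ineq_jac(full_v(L))[:, n_u:]

    nL = prob.nL
    cons = [
        dict(type="ineq", fun=ineq, jac=ineq_jac),
        dict(type="eq", fun=lambda L: L.sum() - gamma,
             jac=lambda L: np.ones((1, nL))),
    ]
    L0 = np.asarray(lengths, dtype=float)
    with np.errstate(all="ignore"):
        res = minimize(
            fun, L0, jac=grad, method="SLSQP",
            bounds=[(hlb, gamma)] * nL, constraints=cons,
            options=dict(maxiter=maxiter, ftol=1e-12),
        )
    L_new, cost0 = res.x, fun(L0)
    ok = (
        np.all(np.isfinite(L_new))
        and ineq(L_new).min() >= -constr_tol
        and abs(L_new.sum() - gamma) <= constr_tol
        and fun(L_new) < cost0
    )
    return (L_new, fun(L_new)) if ok else (L0, cost0)


def project_lengths(L: np.ndarray, total: float, lower: float) -> np.ndarray:
    """Project lengths onto { l >= lower, sum(l) = total }."""
    L = np.clip(np.asarray(L, dtype=float), lower, None)
    for _ in range(50):
        excess = L.sum() - total
        if abs(excess) < 1e-12:
            break
        free = L > lower if excess > 0 else np.ones_like(L, dtype=bool)
        L[free] -= excess / free.sum()
        L = np.clip(L, lower, None)
    return L


def solve_codesign(
    problem: CodesignProblem,
    uniform_result: SolveResult | None = None,
    seed: int = 0,
    maxiter: int = 120,
    coarse_grid: TimeGrid | None = None,
    coarse_maxiter: int = 400,
    fine_maxiter: int = 300,
    n_starts: int = 3,
) -> CodesignResult:
    """Co-design solve: SQP discovery, then a feasible re-track.

    Starting from the uniform-length optimum (computed if not supplied;
    it is feasible for the co-design problem, so the returned cost never
    exceeds it):

    1. a warm full-space SQP over (states, controls, lengths) jointly
       re-optimizes the trajectory and the length allocation; small
       constraint residuals at the iteration cap are repaired (effort
       rescale + defect restoration) and the candidate is kept only if
       it is feasible and better;
    2. a small length-only SQP polishes the lengths with the controls
       frozen (states following through the implicit rollout).

    The best feasible incumbent across the stages is returned.  For a
    fair uniform-vs-co-designed comparison the caller should apply the
    same warm SQP polish to the uniform arm (see
    ``experiment.sqp_polish``), so both arms receive equal optimization
    effort and the difference isolates the morphology.
    """
    from .experiment import solve_tracking  # local import: avoid cycle

    model = problem.model
    target = problem.target
    grid = problem.grid
    gamma = model.params.tail_total_length
    hlb = model.params.min_vertebra_length
    if uniform_result is None:
        uniform_result = solve_tracking(
            build_uniform_model(model.n_vertebrae, model.params), target,
            fine_grid=grid, coarse_grid=coarse_grid, seed=seed,
            coarse_maxiter=coarse_maxiter, fine_maxiter=fine_maxiter,
            n_starts=n_starts,
        )
    L_uni = np.asarray(model.tail.lengths, dtype=float)
    best = dataclasses.replace(
        uniform_result, lengths=L_uni.copy(), init_label="uniform-incumbent",
    )

    # 1. joint discovery SQP from the uniform optimum, run against
    # 1%-tightened bounds so the exact-rollout repair of its controls
    # satisfies the true constraints.  The length start is the uniform
    # allocation plus a small seeded random perturbation: exactly-uniform
    # lengths sit near a symmetric stationary point of the length
    # gradient, where SQP steps stall before the lengths differentiate.
    rng = np.random.default_rng(seed % (2**31))
    L_start = project_lengths(
        L_uni + rng.uniform(-0.02, 0.02, size=L_uni.shape), gamma, hlb
    )
    z0 = problem.pack(uniform_result.states, uniform_result.controls, L_start)
    disc = problem.solve_slsqp(z0, init_label="warm-joint-sqp",
                               maxiter=maxiter, margin=0.01)
    states, controls = uniform_result.states, uniform_result.controls
    if disc.solver_status != "failed" and disc.cost < best.cost:
        best = disc
        states, controls = disc.states, disc.controls

    # 2. length polish with the controls frozen
    L_start = project_lengths(
        best.lengths if best.lengths is not None else L_uni, gamma, hlb
    )
    L2, cost_l = length_step(problem, states, controls, L_start)
    if cost_l < best.cost:
        s = problem._reduced_stage(np.concatenate([controls.ravel(), L2]))
        X_l, U_l, _ = problem.unpack(s["z"])
        viol = problem.constraint_violation(s["z"])
        if viol <= 1e-6:
            best = SolveResult(
                times=problem.grid.knots.copy(), states=X_l, controls=U_l,
                cost=cost_l, solver_status="acceptable",
                init_label="length-polish", iterations=best.iterations,
                constraint_violation=viol, lengths=L2.copy(),
            )
    if best.lengths is None:
        best = dataclasses.replace(best, lengths=L_uni.copy())
    return best
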