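"""Experiment orchestration: reproducible multi-trial optimization runs.

The tracking solves follow a coarse-to-fine protocol: multistart on a
coarse collocation grid (cheap, good global exploration), then one
refinement solve on the target grid warm-started from the interpolated
coarse incumbent.  Profiles bundle the grids, iteration budgets and
start counts:

* ``fast`` — desk-scale: coarse dt = 0.1 s, fine dt = 0.02 s; used by
  the test-suite and the reproduction experiments.
* ``reference`` — full scale: fine dt = 0.004 s, five starts, large
  iteration budgets.  Hours of CPU per bundle; not run by default.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .collocation import CollocationProblem, SolveResult, TimeGrid
from .model import ModelSpec, build_uniform_model, build_variable_model
from .params import DEFAULT_PARAMS, TableParams
from .targets import FourierTargetTrajectory, TrajectoryBundle, bundle

__all__ = [
    "ExperimentProfile",
    "FAST_PROFILE",
    "REFERENCE_PROFILE",
    "solve_tracking",
    "run_uniform_experiment",
    "run_codesign_experiment",
    "ExperimentConfig",
    "run_experiment",
]


@dataclasses.dataclass(frozen=True)
class ExperimentProfile:
    name: str
    fine_grid: TimeGrid
    coarse_grid: TimeGrid | None
    coarse_maxiter: int
    fine_maxiter: int
    n_starts: int
    codesign_maxiter: int

    @classmethod
    def get(cls, name: str) -> "ExperimentProfile":
        try:
            return {"fast": FAST_PROFILE, "reference": REFERENCE_PROFILE}[name]
        except KeyError:
            raise ValueError(f"unknown profile {name!r}") from None


FAST_PROFILE = ExperimentProfile(
    name="fast", fine_grid=TimeGrid(dt=0.02), coarse_grid=TimeGrid(dt=0.1),
    coarse_maxiter=400, fine_maxiter=300, n_starts=3, codesign_maxiter=120,
)
REFERENCE_PROFILE = ExperimentProfile(
    name="reference", fine_grid=TimeGrid(dt=0.004), coarse_grid=TimeGrid(dt=0.02),
    coarse_maxiter=1000, fine_maxiter=3000, n_starts=5, codesign_maxiter=1000,
)


def interpolate_result(
    result: SolveResult, problem: CollocationProblem
) -> np.ndarray:
    """Interpolate a solution onto another grid (as a packed guess)."""
    tf_k = problem.grid.knots
    tc_k = result.times
    X = np.stack(
        [np.interp(tf_k, tc_k, result.states[:, j])
         for j in range(result.states.shape[1])], axis=1,
    )
    U = np.stack(
        [np.interp(tf_k, tc_k, result.controls[:, j])
         for j in range(result.controls.shape[1])], axis=1,
    )
    L = result.lengths if problem.nL else None
    return problem.pack(X, U, L)


def solve_tracking(
    model: ModelSpec,
    target: FourierTargetTrajectory,
    fine_grid: TimeGrid | None = None,
    coarse_grid: TimeGrid | None = None,
    seed: int = 0,
    coarse_maxiter: int = 400,
    fine_maxiter: int = 300,
    n_starts: int = 3,
    profile: ExperimentProfile | str | None = None,
) -> SolveResult:
    """Coarse-to-fine multistart solve of one tracking trial.

    The labelled initial guesses (zeros, linear, random) compete on the
    coarse grid; the best feasible coarse solution is interpolated onto
    the fine grid and refined once.  Falls back to direct fine-grid
    multistart when no coarse solve succeeds.
    """
    if profile is not None:
        prof = (ExperimentProfile.get(profile)
                if isinstance(profile, str) else profile)
        fine_grid = prof.fine_grid
        coarse_grid = prof.coarse_grid
        coarse_maxiter = prof.coarse_maxiter
        fine_maxiter = prof.fine_maxiter
        n_starts = prof.n_starts
    fine = CollocationProblem(model, target, grid=fine_grid)
    if coarse_grid is None:
        return fine.multistart(seed=seed, n_starts=n_starts,
                               method="trust-constr", maxiter=fine_maxiter)
    coarse = CollocationProblem(model, target, grid=coarse_grid)
    results = []
    for label, z0 in coarse.initial_guesses(seed)[:n_starts]:
        try:
            results.append(coarse.solve(
                z0, init_label=label, method="trust-constr",
                maxiter=coarse_maxiter,
            ))
        except Exception:
            continue
    ok = [r for r in results if r.solver_status != "failed"]
    if not ok:
        return fine.multistart(seed=seed, n_starts=n_starts,
                               method="trust-constr", maxiter=fine_maxiter)
    best_coarse = min(ok, key=lambda r: r.cost)
    guess = interpolate_result(best_coarse, fine)
    refined = fine.solve(
        guess, init_label=f"coarse-{best_coarse.init_label}",
        method="trust-constr", maxiter=fine_maxiter,
    )
    return refined


def sqp_polish(
    model: ModelSpec,
    target: FourierTargetTrajectory,
    result: SolveResult,
    grid: TimeGrid,
    maxiter: int = 80,
    margin: float = 0.01,
) -> SolveResult:
    """Warm full-space SQP refinement of a solved tracking trial.

    Used to equalize optimization effort between the uniform and
    co-designed arms of the paired comparison: the co-design pipeline
    includes a warm joint SQP, so the uniform baseline receives the same
    refinement (lengths held fixed).  Returns the better feasible of the
    input and the refined result.
    """
    problem = CollocationProblem(model, target, grid=grid)
    z0 = problem.pack(result.states, result.controls)
    refined = problem.solve_slsqp(z0, init_label=f"{result.init_label}+sqp",
                                  maxiter=maxiter, margin=margin)
    if refined.solver_status != "failed" and refined.cost < result.cost:
        return refined
    return result


def run_uniform_experiment(
    ns: list[int],
    trajectory_bundle: TrajectoryBundle,
    profile: ExperimentProfile | str = "fast",
    params: TableParams = DEFAULT_PARAMS,
    progress: bool = False,
) -> pd.DataFrame:
    """Solve every (n, trajectory) pair; tidy per-trial metrics table."""
    from .analysis import metrics_table, trial_metrics

    prof = (ExperimentProfile.get(profile)
            if isinstance(profile, str) else profile)
    metrics = []
    for n in ns:
        model = build_uniform_model(n, params)
        for i, target in enumerate(trajectory_bundle):
            seed = trajectory_bundle.seed ^ (97 * i) ^ (1031 * n)
            result = solve_tracking(model, target, profile=prof, seed=seed)
            metrics.append(trial_metrics(model, result,
                                         trajectory_id=i, seed=seed))
            if progress:
                print(f"uniform n={n} traj={i}: cost={result.cost:.6f} "
                      f"[{result.solver_status}]", flush=True)
    return metrics_table(metrics)


def run_codesign_experiment(
    ns: list[int],
    trajectory_bundle: TrajectoryBundle,
    profile: ExperimentProfile | str = "fast",
    params: TableParams = DEFAULT_PARAMS,
    progress: bool = False,
) -> pd.DataFrame:
    """Uniform and co-designed solves per (n, trajectory); paired table."""
    from .analysis import trial_metrics
    from .codesign import solve_codesign, transcribe_codesign

    prof = (ExperimentProfile.get(profile)
            if isinstance(profile, str) else profile)
    rows = []
    for n in ns:
        model = build_uniform_model(n, params)
        for i, target in enumerate(trajectory_bundle):
            seed = trajectory_bundle.seed ^ (97 * i) ^ (1031 * n)
            uni = solve_tracking(model, target, profile=prof, seed=seed)
            # equal refinement budget for both arms of the pairing
            uni = sqp_polish(model, target, uni, prof.fine_grid,
                             maxiter=prof.codesign_maxiter)
            problem = transcribe_codesign(n, target, grid=prof.fine_grid,
                                          params=params)
            var = solve_codesign(
                problem, uniform_result=uni, seed=seed,
                coarse_grid=prof.coarse_grid,
                coarse_maxiter=prof.coarse_maxiter,
                fine_maxiter=prof.fine_maxiter,
                n_starts=prof.n_starts,
                maxiter=prof.codesign_maxiter,
            )
            mu = trial_metrics(model, uni, trajectory_id=i, seed=seed)
            mv = trial_metrics(build_variable_model(var.lengths, params), var,
                               trajectory_id=i, seed=seed)
            row = {
                "n_vertebrae": n, "trajectory_id": i, "seed": seed,
                "uniform_error": mu.tracking_error,
                "variable_error": mv.tracking_error,
                "uniform_max_tip_speed": mu.max_tip_speed,
                "variable_max_tip_speed": mv.max_tip_speed,
            }
            for j, length in enumerate(var.lengths):
                row[f"length_{j + 1}"] = float(length)
            for j, e in enumerate(mu.per_joint_effort):
                row[f"uniform_effort_joint_{j + 1}"] = e
            for j, e in enumerate(mv.per_joint_effort):
                row[f"variable_effort_joint_{j + 1}"] = e
            rows.append(row)
            if progress:
                print(f"codesign n={n} traj={i}: uniform={uni.cost:.6f} "
                      f"variable={var.cost:.6f}", flush=True)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ExperimentConfig:
    """Serializable description of one full experiment run."""

    root_seed: int = 0
    profile: str = "fast"
    uniform_ns: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    codesign_ns: tuple[int, ...] = (2, 3, 4)
    bundle_count: int = 10
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_experiment(config: ExperimentConfig, progress: bool = False) -> Path:
    """Run the full uniform + co-design experiment and archive results.

    Writes the resolved config, the trajectory bundle, tidy metric CSVs
    and a manifest into ``config.out_dir``.  Already-archived tables are
    not recomputed (idempotent re-runs).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    tb = bundle(seed=config.root_seed, count=config.bundle_count)
    tb.to_json(out / "targets.json")

    uniform_csv = out / "uniform_metrics.csv"
    if not uniform_csv.exists():
        df = run_uniform_experiment(list(config.uniform_ns), tb,
                                    profile=config.profile, progress=progress)
        df.to_csv(uniform_csv, index=False)
    codesign_csv = out / "codesign_metrics.csv"
    if not codesign_csv.exists():
        df = run_codesign_experiment(list(config.codesign_ns), tb,
                                     profile=config.profile,
                                     progress=progress)
        df.to_csv(codesign_csv, index=False)

    manifest = {
        "config": config.to_dict(),
        "files": {},
    }
    for f in sorted(out.glob("*.csv")) + [out / "targets.json"]:
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
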