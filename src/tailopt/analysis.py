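"""Per-trial performance metrics and cross-configuration statistics.

For each solved (model, target) pair the metrics are

* the integrated tracking error (the optimization objective itself,
  rad^2 s),
* the maximum tail-tip speed over the horizon (m/s), and
* per-joint control-effort integrals (N^2 m^2 s): the time integral of
  the summed squared pitch + yaw torques of each 2-DOF joint.

Across configurations the statistics mirror standard comparative
practice: one-way ANOVA with Tukey HSD post-hoc tests over the number
of vertebrae, and paired t-tests for uniform-vs-optimized vertebral
lengths on a shared trajectory bundle.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .collocation import CollocationProblem, SolveResult
from .dynamics import ChainDynamics
from .model import ModelSpec
from .targets import FourierTargetTrajectory

__all__ = [
    "TrialMetrics",
    "tracking_error",
    "improvement_percent",
    "max_tip_speed",
    "joint_effort_integrals",
    "trial_metrics",
    "compare_uniform_configs",
    "compare_paired",
    "significance_symbol",
]


@dataclasses.dataclass(frozen=True)
class TrialMetrics:
    """Scalar performance summary of one solved trial."""

    tracking_error: float           # rad^2 s
    max_tip_speed: float            # m/s
    per_joint_effort: tuple[float, ...]  # N^2 m^2 s, proximal -> distal
    n_vertebrae: int
    design: str                     # "uniform" | "variable"
    trajectory_id: int
    seed: int


def tracking_error(
    result: SolveResult,
    target: FourierTargetTrajectory,
    problem: CollocationProblem | None = None,
) -> float:
    """Simpson quadrature of ||C x(t) - Theta(t)||^2 on the solve grid.

    Uses the Hermite midpoint states implied by the solution (the same
    quadrature as the solver objective), so it reproduces
    ``SolveResult.cost`` exactly on a solved trial.
    """
    if problem is not None:
        return problem.objective(problem.pack(
            result.states, result.controls,
            result.lengths if problem.nL else None,
        ))
    times = result.times
    dt = times[1] - times[0]
    theta_k, _ = target.evaluate(times)
    e_k = np.sum((result.states[:, :3] - theta_k) ** 2, axis=1)
    # Hermite midpoint states are not available without the dynamics;
    # fall back to the interpolated midpoint of the orientation states
    theta_m, _ = target.evaluate(times[:-1] + dt / 2.0)
    xm = 0.5 * (result.states[:-1, :3] + result.states[1:, :3])
    e_m = np.sum((xm - theta_m) ** 2, axis=1)
    return float(dt / 6.0 * np.sum(e_k[:-1] + 4.0 * e_m + e_k[1:]))


def improvement_percent(err_ref: float, err_new: float) -> float:
    """Percentage reduction of ``err_new`` relative to ``err_ref``."""
    if err_ref <= 0.0:
        raise ValueError("reference error must be positive")
    return 100.0 * (1.0 - err_new / err_ref)


def max_tip_speed(model: ModelSpec, result: SolveResult) -> float:
    """Maximum norm of the tail-tip linear velocity over the knots."""
    dyn = ChainDynamics(model)
    nq = model.nq
    _, speed = dyn.tip_velocity(
        result.states[:, :nq], result.states[:, nq:], result.lengths
    )
    return float(np.max(speed))


def joint_effort_integrals(result: SolveResult) -> np.ndarray:
    """Per-joint integral of squared pitch + yaw torques (trapezoid rule)."""
    U = result.controls
    n_joints = U.shape[1] // 2
    per_joint = U.reshape(U.shape[0], n_joints, 2)
    inst = np.sum(per_joint**2, axis=2)  # (knots, joints)
    return np.trapezoid(inst, result.times, axis=0)


def trial_metrics(
    model: ModelSpec,
    result: SolveResult,
    trajectory_id: int = 0,
    seed: int = 0,
) -> TrialMetrics:
    design = "variable" if result.lengths is not None and np.ptp(
        result.lengths
    ) > 1e-9 else "uniform"
    return TrialMetrics(
        tracking_error=float(result.cost),
        max_tip_speed=max_tip_speed(model, result),
        per_joint_effort=tuple(joint_effort_integrals(result)),
        n_vertebrae=model.n_vertebrae,
        design=design,
        trajectory_id=trajectory_id,
        seed=seed,
    )


def significance_symbol(p: float) -> str:
    """Symbol scheme used in the pairwise significance tables."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "()"


def compare_uniform_configs(
    errors_by_n: dict[int, Sequence[float]],
) -> dict:
    """One-way ANOVA + Tukey HSD over the number of vertebrae.

    ``errors_by_n`` maps vertebra count to per-trajectory metric values
    (tracking error or max tip speed) over a shared bundle.  Returns the
    ANOVA F, degrees of freedom and p-value, plus a tidy DataFrame of
    pairwise Tukey HSD p-values with significance symbols.
    """
    ns = sorted(errors_by_n)
    if len(ns) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(errors_by_n[n], dtype=float) for n in ns]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    F, p = stats.f_oneway(*groups)
    tuk = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(ns)):
        for j in range(i):
            pij = float(tuk.pvalue[i, j])
            rows.append({
                "n_a": ns[j], "n_b": ns[i], "p": pij,
                "symbol": significance_symbol(pij),
            })
    k = len(ns)
    n_tot = sum(len(g) for g in groups)
    return {
        "F": float(F),
        "df_between": k - 1,
        "df_within": n_tot - k,
        "p": float(p),
        "tukey": pd.DataFrame(rows),
    }


def compare_paired(
    uniform: Sequence[float], variable: Sequence[float]
) -> dict:
    """Classical paired t-test on per-trajectory metric differences."""
    a = np.asarray(uniform, dtype=float)
    b = np.asarray(variable, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.ptp(d) == 0.0 and np.any(d != 0.0):
        # constant nonzero difference: t is unbounded
        return {"t": np.inf, "df": len(d) - 1, "p": 0.0, "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": len(d) - 1, "p": float(p),
            "degenerate": False}


def metrics_table(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    """Tidy per-trial table (one row per trial)."""
    rows = []
    for m in metrics:
        row = dataclasses.asdict(m)
        effort = row.pop("per_joint_effort")
        row["total_effort"] = float(np.sum(effort))
        for j, e in enumerate(effort):
            row[f"effort_joint_{j + 1}"] = e
        rows.append(row)
    return pd.DataFrame(rows)
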