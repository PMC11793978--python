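"""Random target torso-orientation trajectories.

Each target is a fifth-degree Fourier series per axis (roll, pitch,
yaw),

    theta_i(t) = a_i0 + sum_{j=1..5} a_ij cos(j w_i t) + b_ij sin(j w_i t),

with a_i0 = -sum_j a_ij so every trajectory starts at zero orientation.
Coefficients are sampled randomly and rescaled so that, on a dense time
grid, |theta_i| <= 180 deg and |theta_i'| <= 360 deg/s with a safety
margin — the same bounds the torso states must satisfy.  The resulting
0.5 s trajectories contain large accelerations in all three axes, like
the rotations an animal experiences when banking or preparing a leap.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .params import DEG

__all__ = [
    "FourierTargetTrajectory",
    "TrajectoryBundle",
    "sample_trajectory",
    "bundle",
]

N_HARMONICS = 5

#: sampling distribution defaults (artifact choices, exposed for study)
OMEGA_RANGE = (2.0 * math.pi * 0.5, 2.0 * math.pi * 2.0)  # rad/s
PEAK_RANGE = (30.0 * DEG, 170.0 * DEG)  # target per-axis peak |theta|
BOUND_MARGIN = 0.95
ANGLE_BOUND = 180.0 * DEG
RATE_BOUND = 360.0 * DEG
_DENSE_DT = 1e-3


@dataclasses.dataclass(frozen=True)
class FourierTargetTrajectory:
    """Target orientation trajectory Theta(t) on [t0, tf].

    ``a`` has shape (3, 6) with a[:, 0] = a_i0; ``b`` has shape (3, 5);
    ``omega`` shape (3,).  Angles in rad, times in s.
    """

    a: np.ndarray
    b: np.ndarray
    omega: np.ndarray
    t0: float = 0.0
    tf: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        if self.a.shape != (3, N_HARMONICS + 1) or self.b.shape != (3, N_HARMONICS):
            raise ValueError("coefficient arrays must be (3,6) and (3,5)")
        if not self.tf > self.t0:
            raise ValueError("tf must exceed t0")

    def evaluate(self, t):
        """Closed-form Theta(t) and its analytic derivative.

        ``t`` may be scalar or an array within [t0, tf]; returns arrays
        of shape t.shape + (3,) in rad and rad/s.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0 - 1e-12) or np.any(t > self.tf + 1e-12):
            raise ValueError(f"time outside trajectory horizon [{self.t0}, {self.tf}]")
        j = np.arange(1, N_HARMONICS + 1)
        phase = j * self.omega[:, None] * t[..., None, None]  # t... x 3 x 5
        cos, sin = np.cos(phase), np.sin(phase)
        theta = (
            self.a[:, 0]
            + np.sum(self.a[:, 1:] * cos, axis=-1)
            + np.sum(self.b * sin, axis=-1)
        )
        jw = j * self.omega[:, None]
        dtheta = np.sum(-self.a[:, 1:] * jw * sin, axis=-1) + np.sum(
            self.b * jw * cos, axis=-1
        )
        return theta, dtheta

    def dense_grid(self, dt: float = _DENSE_DT):
        n = max(2, int(round((self.tf - self.t0) / dt)) + 1)
        return np.linspace(self.t0, self.tf, n)

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "omega": self.omega.tolist(),
            "t0": self.t0,
            "tf": self.tf,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FourierTargetTrajectory":
        return cls(
            a=np.array(d["a"]), b=np.array(d["b"]), omega=np.array(d["omega"]),
            t0=float(d["t0"]), tf=float(d["tf"]),
        )


def sample_trajectory(
    seed_or_rng, t0: float = 0.0, tf: float = 0.5
) -> FourierTargetTrajectory:
    """Draw one random bounded target trajectory.

    Per axis: a_ij, b_ij ~ U[-1, 1], omega_i ~ U(OMEGA_RANGE), then the
    j>=1 coefficients are rescaled so the dense-grid peak of |theta_i|
    equals a random value in PEAK_RANGE, and rescaled again if needed so
    the peak rate respects the velocity bound with margin.  Finally
    a_i0 = -sum_j a_ij makes theta_i(t0) = 0 exactly.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    a = np.zeros((3, N_HARMONICS + 1))
    a[:, 1:] = rng.uniform(-1.0, 1.0, size=(3, N_HARMONICS))
    b = rng.uniform(-1.0, 1.0, size=(3, N_HARMONICS))
    omega = rng.uniform(*OMEGA_RANGE, size=3)
    peaks = rng.uniform(*PEAK_RANGE, size=3)

    traj = FourierTargetTrajectory(a=a, b=b, omega=omega, t0=t0, tf=tf)
    grid = traj.dense_grid()
    # theta is linear in the j>=1 coefficients (with a_i0 tied to them),
    # so a per-axis scale factor moves the peak exactly
    a0 = -a[:, 1:].sum(axis=1)
    theta, dtheta = FourierTargetTrajectory(
        a=np.column_stack([a0, a[:, 1:]]), b=b, omega=omega, t0=t0, tf=tf
    ).evaluate(grid)
    max_theta = np.max(np.abs(theta), axis=0)
    max_rate = np.max(np.abs(dtheta), axis=0)
    scale = np.where(max_theta > 0, peaks / np.maximum(max_theta, 1e-30), 0.0)
    scale = np.minimum(
        scale, BOUND_MARGIN * RATE_BOUND / np.maximum(max_rate, 1e-30)
    )
    scale = np.minimum(
        scale, BOUND_MARGIN * ANGLE_BOUND / np.maximum(max_theta, 1e-30)
    )
    a[:, 1:] *= scale[:, None]
    b *= scale[:, None]
    a[:, 0] = -a[:, 1:].sum(axis=1)
    return FourierTargetTrajectory(a=a, b=b, omega=omega, t0=t0, tf=tf)


@dataclasses.dataclass(frozen=True)
class TrajectoryBundle:
    """A reproducible set of target trajectories drawn from one seed."""

    trajectories: tuple[FourierTargetTrajectory, ...]
    seed: int
    count: int

    def __post_init__(self):
        if len(self.trajectories) != self.count:
            raise ValueError("count does not match trajectory list")

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return self.count

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "seed": self.seed,
            "count": self.count,
            "trajectories": [t.to_dict() for t in self.trajectories],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrajectoryBundle":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            trajectories=tuple(
                FourierTargetTrajectory.from_dict(d) for d in doc["trajectories"]
            ),
            seed=int(doc["seed"]),
            count=int(doc["count"]),
        )


def bundle(
    seed: int, count: int = 100, t0: float = 0.0, tf: float = 0.5
) -> TrajectoryBundle:
    """Deterministically generate ``count`` target trajectories."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    trajs = tuple(sample_trajectory(rng, t0=t0, tf=tf) for _ in range(count))
    return TrajectoryBundle(trajectories=trajs, seed=seed, count=count)
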