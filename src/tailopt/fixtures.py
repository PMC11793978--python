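"""Deterministic fixture generation for tests and demos.

Everything the test-suite consumes is generated here at run time from a
seed: small models, URDF files, tiny target bundles (including the
exact-zero target, for which the optimal cost is analytically zero),
2-interval grids for hand-checkable transcriptions, and synthetic
morphometric tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .collocation import TimeGrid
from .model import ModelSpec, build_uniform_model, build_variable_model
from .morphometrics import synthetic_table
from .targets import FourierTargetTrajectory, TrajectoryBundle, bundle
from .urdf import to_urdf

__all__ = ["zero_target", "tiny_grid", "make_fixtures", "FixtureSet"]


def zero_target(t0: float = 0.0, tf: float = 0.5) -> FourierTargetTrajectory:
    """The identically-zero target: reachable exactly with zero control."""
    return FourierTargetTrajectory(
        a=np.zeros((3, 6)), b=np.zeros((3, 5)),
        omega=np.full(3, 2.0 * np.pi), t0=t0, tf=tf,
    )


def tiny_grid(n_intervals: int = 2, t0: float = 0.0,
              tf: float = 0.5) -> TimeGrid:
    """A grid small enough for analytic checks of the transcription."""
    return TimeGrid(t0=t0, tf=tf, dt=(tf - t0) / n_intervals)


@dataclasses.dataclass(frozen=True)
class FixtureSet:
    models: dict[str, ModelSpec]
    urdf_paths: dict[str, Path]
    bundle: TrajectoryBundle
    zero_target: FourierTargetTrajectory
    grid: TimeGrid
    morphometrics_csv: Path
    worked_example_csv: Path


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures",
                  bundle_count: int = 3) -> FixtureSet:
    """Write the deterministic fixture set used by the tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = {
        "uniform_1": build_uniform_model(1),
        "uniform_2": build_uniform_model(2),
        "uniform_6": build_uniform_model(6),
        "variable_3": build_variable_model([0.3, 0.7, 0.5]),
    }
    urdf_paths = {}
    for name, model in models.items():
        path = out / f"{name}.urdf"
        to_urdf(model, path)
        urdf_paths[name] = path

    tb = bundle(seed=seed, count=bundle_count)
    tb.to_json(out / "targets.json")

    morph = synthetic_table(seed=seed)
    morph_csv = out / "vertebrae_synthetic.csv"
    morph.to_csv(morph_csv, index=False)

    # the printed worked example: lengths (2,4,6,4,2) normalize to
    # (1,2,3,2,1) with max neighbour difference 1
    worked = pd.DataFrame({
        "species": ["example_sp"] * 5,
        "group": ["inertial"] * 5,
        "position": [1, 2, 3, 4, 5],
        "length_mm": [2.0, 4.0, 6.0, 4.0, 2.0],
    })
    worked_csv = out / "vertebrae_worked_example.csv"
    worked.to_csv(worked_csv, index=False)

    return FixtureSet(
        models=models, urdf_paths=urdf_paths, bundle=tb,
        zero_target=zero_target(), grid=tiny_grid(),
        morphometrics_csv=morph_csv, worked_example_csv=worked_csv,
    )
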