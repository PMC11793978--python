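"""Parametric torso + tail rigid-body models.

A model is a floating torso (uniformly dense square prism, pinned to the
ground through an unactuated 3-DOF rotational joint at its centroid) with
a serial tail of ``n`` vertebrae.  Each vertebra is a uniformly dense
square prism whose long axis is the local y axis; consecutive bodies are
connected by 2-DOF (pitch then yaw) actuated joints placed at the prism
end faces.  All tails share the same total length and total mass, so the
per-vertebra mass is proportional to its length (fixed cross-section,
uniform density).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .params import DEFAULT_PARAMS, TableParams

__all__ = [
    "BodyGeometry",
    "JointLimits",
    "TailDesign",
    "ModelSpec",
    "prism_inertia",
    "build_uniform_model",
    "build_variable_model",
    "collision_spheres",
    "InvalidGeometryError",
]

_LENGTH_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions/masses or inconsistent designs."""


@dataclasses.dataclass(frozen=True)
class BodyGeometry:
    """A uniformly dense rectangular prism.

    ``width``, ``length``, ``height`` are the extents along the local
    x, y, z axes (m); ``length`` is the long axis for torso and
    vertebrae.  ``mass`` in kg.
    """

    width: float
    length: float
    height: float
    mass: float

    def __post_init__(self) -> None:
        for name in ("width", "length", "height", "mass"):
            if not getattr(self, name) > 0.0:
                raise InvalidGeometryError(
                    f"BodyGeometry.{name} must be strictly positive, "
                    f"got {getattr(self, name)!r}"
                )


@dataclasses.dataclass(frozen=True)
class JointLimits:
    """Per-DOF limits for the actuated tail joints.

    Angles in rad, velocities in rad/s, torques in Nm.  Intervals are
    symmetric in the reference model but stored as (lower, upper).
    """

    position_range: tuple[float, float] = (
        -DEFAULT_PARAMS.joint_position_limit,
        DEFAULT_PARAMS.joint_position_limit,
    )
    velocity_range: tuple[float, float] = (
        -DEFAULT_PARAMS.joint_velocity_limit,
        DEFAULT_PARAMS.joint_velocity_limit,
    )
    torque_range: tuple[float, float] = (
        -DEFAULT_PARAMS.joint_torque_limit,
        DEFAULT_PARAMS.joint_torque_limit,
    )

    def __post_init__(self) -> None:
        for name in ("position_range", "velocity_range", "torque_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidGeometryError(
                    f"JointLimits.{name} lower bound must be < upper bound"
                )


@dataclasses.dataclass(frozen=True)
class TailDesign:
    """A tail as an ordered sequence of vertebral prisms.

    ``lengths`` are proximal-to-distal vertebral lengths (m), summing to
    ``total_length``.  Mass is distributed proportionally to length
    (uniform density at fixed square cross-section).
    """

    lengths: tuple[float, ...]
    total_length: float
    total_mass: float
    cross_section: float
    min_length: float = DEFAULT_PARAMS.min_vertebra_length

    def __post_init__(self) -> None:
        if len(self.lengths) < 1:
            raise InvalidGeometryError("tail needs at least one vertebra")
        if any(not length > 0.0 for length in self.lengths):
            raise InvalidGeometryError("vertebral lengths must be positive")
        if abs(math.fsum(self.lengths) - self.total_length) > _LENGTH_TOL:
            raise InvalidGeometryError(
                f"vertebral lengths sum to {math.fsum(self.lengths)!r}, "
                f"expected total {self.total_length!r}"
            )

    @property
    def n_vertebrae(self) -> int:
        return len(self.lengths)

    @property
    def masses(self) -> tuple[float, ...]:
        """Per-vertebra masses, proportional to length."""
        scale = self.total_mass / self.total_length
        return tuple(length * scale for length in self.lengths)

    def geometries(self) -> tuple[BodyGeometry, ...]:
        cs = self.cross_section
        return tuple(
            BodyGeometry(width=cs, length=length, height=cs, mass=mass)
            for length, mass in zip(self.lengths, self.masses)
        )


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Complete description of one torso + tail model.

    The unactuated base decomposes the torso orientation as intrinsic
    Z-Y-X (yaw, pitch, roll); configuration vector q has nq = 2*n + 3
    entries: (roll, pitch, yaw, pitch_1, yaw_1, ..., pitch_n, yaw_n).
    Each 2-DOF tail joint is a pitch (local x) joint followed by a yaw
    (local z) joint at the same point.
    """

    torso: BodyGeometry
    tail: TailDesign
    joint_limits: JointLimits = JointLimits()
    joint_axis_order: str = "pitch-then-yaw"
    base_euler_convention: str = "intrinsic-zyx"
    params: TableParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if self.joint_axis_order not in ("pitch-then-yaw", "yaw-then-pitch"):
            raise InvalidGeometryError(
                f"unknown joint_axis_order {self.joint_axis_order!r}"
            )
        if self.base_euler_convention != "intrinsic-zyx":
            raise InvalidGeometryError(
                f"unsupported base_euler_convention "
                f"{self.base_euler_convention!r}"
            )

    @property
    def n_vertebrae(self) -> int:
        return self.tail.n_vertebrae

    @property
    def nq(self) -> int:
        """Configuration dimension: 3 base DOF + 2 per vertebra."""
        return 2 * self.n_vertebrae + 3

    @property
    def nu(self) -> int:
        """Number of actuated DOF (all tail joints)."""
        return self.nq - 3


def prism_inertia(geom: BodyGeometry) -> np.ndarray:
    """Centroidal inertia tensor of a uniformly dense rectangular prism.

    Returns the 3x3 tensor in body axes (kg m^2):
    diag(m/12 (l^2 + h^2), m/12 (w^2 + h^2), m/12 (w^2 + l^2)).
    """
    w, length, h, m = geom.width, geom.length, geom.height, geom.mass
    return np.diag(
        [
            m / 12.0 * (length**2 + h**2),
            m / 12.0 * (w**2 + h**2),
            m / 12.0 * (w**2 + length**2),
        ]
    )


def _torso_geometry(params: TableParams) -> BodyGeometry:
    return BodyGeometry(
        width=params.torso_width,
        length=params.torso_length,
        height=params.torso_height,
        mass=params.torso_mass,
    )


def _limits_from(params: TableParams) -> JointLimits:
    return JointLimits(
        position_range=(-params.joint_position_limit, params.joint_position_limit),
        velocity_range=(-params.joint_velocity_limit, params.joint_velocity_limit),
        torque_range=(-params.joint_torque_limit, params.joint_torque_limit),
    )


def build_uniform_model(
    n_vertebrae: int, params: TableParams = DEFAULT_PARAMS
) -> ModelSpec:
    """Model with ``n_vertebrae`` equal-length vertebrae."""
    if n_vertebrae < 1:
        raise InvalidGeometryError("n_vertebrae must be >= 1")
    lengths = (params.tail_total_length / n_vertebrae,) * n_vertebrae
    return build_variable_model(lengths, params)


def build_variable_model(
    lengths: Sequence[float], params: TableParams = DEFAULT_PARAMS
) -> ModelSpec:
    """Model with the given proximal-to-distal vertebral lengths.

    The lengths must sum to the fixed total tail length; mass and
    inertia of each vertebra follow from its length at uniform density.
    """
    tail = TailDesign(
        lengths=tuple(float(length) for length in lengths),
        total_length=params.tail_total_length,
        total_mass=params.tail_total_mass,
        cross_section=params.tail_cross_section,
        min_length=params.min_vertebra_length,
    )
    return ModelSpec(
        torso=_torso_geometry(params),
        tail=tail,
        joint_limits=_limits_from(params),
        params=params,
    )


@dataclasses.dataclass(frozen=True)
class CollisionSphere:
    """A sphere rigidly attached to a link.

    ``link`` is "torso" or ``("vertebra", i)`` flattened to
    ``"vertebra_i"``; ``offset`` is the centre in the link's joint frame
    (for the torso: the base frame at the torso centroid).
    """

    link: str
    offset: tuple[float, float, float]
    radius: float


def collision_spheres(model: ModelSpec) -> list[CollisionSphere]:
    """Sphere over-approximation used by the self-collision constraints.

    The torso is covered by a row of spheres along its long axis (every
    prism vertex lies inside some sphere); the tail carries one sphere
    at each joint connection and one at the tip.
    """
    params = model.params
    spheres: list[CollisionSphere] = []
    n_torso = params.torso_sphere_count
    r_t = params.torso_sphere_radius
    half = model.torso.length / 2.0
    # evenly spaced centres covering [-0.75, 0.75] * half along y
    if n_torso == 1:
        centres = [0.0]
    else:
        centres = list(np.linspace(-0.75 * half, 0.75 * half, n_torso))
    for c in centres:
        spheres.append(CollisionSphere("torso", (0.0, float(c), 0.0), r_t))
    # one sphere at each tail joint (proximal end of each vertebra) ...
    r_tail = params.tail_sphere_radius
    for i in range(model.n_vertebrae):
        spheres.append(CollisionSphere(f"vertebra_{i}", (0.0, 0.0, 0.0), r_tail))
    # ... and one at the tail tip (distal end of the last vertebra)
    tip_link = model.n_vertebrae - 1
    spheres.append(
        CollisionSphere(
            f"vertebra_{tip_link}",
            (0.0, -model.tail.lengths[-1], 0.0),
            r_tail,
        )
    )
    return spheres
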