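"""URDF serialization of torso + tail models.

The emitted document is plain URDF: every 2-DOF tail joint appears as
two stacked revolute joints (pitch about x, then yaw about z) separated
by a zero-length, massless intermediate link, and the unactuated base
appears as three stacked revolute joints (yaw, pitch, roll — the
intrinsic Z-Y-X decomposition) connecting a ``world`` link to the torso.
Box collision geometry carries the prism dimensions so that the
round-trip ``from_urdf(to_urdf(m))`` reproduces the model exactly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .model import (
    BodyGeometry,
    InvalidGeometryError,
    JointLimits,
    ModelSpec,
    TailDesign,
    prism_inertia,
)
from .params import DEFAULT_PARAMS, TableParams

__all__ = ["to_urdf", "from_urdf", "UrdfParseError"]


class UrdfParseError(ValueError):
    """Malformed or unsupported URDF document; names the offending element."""


def _inertial(parent: ET.Element, geom: BodyGeometry) -> None:
    inertial = ET.SubElement(parent, "inertial")
    ET.SubElement(inertial, "origin", xyz="0 0 0", rpy="0 0 0")
    ET.SubElement(inertial, "mass", value=repr(geom.mass))
    inertia = prism_inertia(geom)
    ET.SubElement(
        inertial, "inertia",
        ixx=repr(inertia[0, 0]), iyy=repr(inertia[1, 1]), izz=repr(inertia[2, 2]),
        ixy="0", ixz="0", iyz="0",
    )


def _box(parent: ET.Element, geom: BodyGeometry, y_offset: float) -> None:
    coll = ET.SubElement(parent, "collision")
    ET.SubElement(coll, "origin", xyz=f"0 {y_offset!r} 0", rpy="0 0 0")
    g = ET.SubElement(coll, "geometry")
    ET.SubElement(g, "box", size=f"{geom.width!r} {geom.length!r} {geom.height!r}")


def _revolute(
    parent_el: ET.Element,
    name: str,
    parent: str,
    child: str,
    axis: tuple[float, float, float],
    xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    limits: JointLimits | None = None,
) -> None:
    j = ET.SubElement(parent_el, "joint", name=name, type="revolute")
    ET.SubElement(j, "parent", link=parent)
    ET.SubElement(j, "child", link=child)
    ET.SubElement(j, "origin", xyz=" ".join(repr(v) for v in xyz), rpy="0 0 0")
    ET.SubElement(j, "axis", xyz=" ".join(repr(float(v)) for v in axis))
    if limits is None:
        # unactuated base joint: full revolution, no actuation effort
        ET.SubElement(j, "limit", lower=repr(-np.pi), upper=repr(np.pi),
                      effort="0", velocity=repr(2 * np.pi))
    else:
        ET.SubElement(
            j, "limit",
            lower=repr(limits.position_range[0]),
            upper=repr(limits.position_range[1]),
            effort=repr(limits.torque_range[1]),
            velocity=repr(limits.velocity_range[1]),
        )


def to_urdf(model: ModelSpec, path: str | Path | None = None) -> str:
    """Serialize a model to a URDF document (returned as a string)."""
    robot = ET.Element("robot", name=f"tail_{model.n_vertebrae}_vertebrae")
    ET.SubElement(robot, "link", name="world")
    # unactuated 3-DOF base: yaw (z), pitch (y), roll (x)
    for name, axis in (("base_yaw", (0, 0, 1)), ("base_pitch", (0, 1, 0))):
        ET.SubElement(robot, "link", name=f"{name}_frame")
    torso = ET.SubElement(robot, "link", name="torso")
    _inertial(torso, model.torso)
    _box(torso, model.torso, 0.0)
    _revolute(robot, "base_yaw", "world", "base_yaw_frame", (0, 0, 1))
    _revolute(robot, "base_pitch", "base_yaw_frame", "base_pitch_frame", (0, 1, 0))
    _revolute(robot, "base_roll", "base_pitch_frame", "torso", (1, 0, 0))

    lim = model.joint_limits
    parent = "torso"
    prev_offset = (0.0, -model.torso.length / 2.0, 0.0)
    for i, geom in enumerate(model.tail.geometries()):
        mid = f"vertebra_{i}_pitch_frame"
        ET.SubElement(robot, "link", name=mid)
        vert = ET.SubElement(robot, "link", name=f"vertebra_{i}")
        _inertial(vert, geom)
        _box(vert, geom, -geom.length / 2.0)
        _revolute(robot, f"tail_{i}_pitch", parent, mid, (1, 0, 0),
                  xyz=prev_offset, limits=lim)
        _revolute(robot, f"tail_{i}_yaw", mid, f"vertebra_{i}", (0, 0, 1),
                  limits=lim)
        parent = f"vertebra_{i}"
        prev_offset = (0.0, -geom.length, 0.0)

    ET.indent(robot)
    text = ET.tostring(robot, encoding="unicode", xml_declaration=False)
    text = '<?xml version="1.0"?>\n' + text + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _req(el: ET.Element, tag: str, context: str) -> ET.Element:
    child = el.find(tag)
    if child is None:
        raise UrdfParseError(f"missing <{tag}> in <{context}>")
    return child


def _floats(text: str, context: str) -> list[float]:
    try:
        return [float(tok) for tok in text.split()]
    except (AttributeError, ValueError) as exc:
        raise UrdfParseError(f"bad numeric attribute in {context}: {text!r}") from exc


def from_urdf(source: str | Path, params: TableParams | None = None) -> ModelSpec:
    """Reconstruct a :class:`ModelSpec` from a URDF document.

    Accepts a path or the document text.  The document must follow the
    structure written by :func:`to_urdf` (serial pitch/yaw tail chain on
    a 3-DOF base); real (massive) links without inertial data are
    rejected.
    """
    s = str(source)
    if "<" in s:
        text = s
    else:
        text = Path(s).read_text()
    try:
        robot = ET.fromstring(text)
    except ET.ParseError as exc:
        raise UrdfParseError(f"not well-formed XML: {exc}") from exc
    if robot.tag != "robot":
        raise UrdfParseError(f"root element is <{robot.tag}>, expected <robot>")

    links = {}
    for link in robot.findall("link"):
        name = link.get("name")
        if name is None:
            raise UrdfParseError("link without a name attribute")
        links[name] = link

    def link_props(name: str):
        link = links[name]
        inertial = link.find("inertial")
        box = link.find("collision/geometry/box")
        if inertial is None or box is None:
            raise UrdfParseError(
                f"link {name!r} lacks inertial/collision data"
            )
        mass = float(_req(inertial, "mass", name).get("value"))
        size = _floats(box.get("size"), f"box of {name!r}")
        if mass <= 0.0:
            raise UrdfParseError(f"link {name!r} has non-positive mass")
        return BodyGeometry(width=size[0], length=size[1], height=size[2],
                            mass=mass)

    if "torso" not in links:
        raise UrdfParseError("document has no <link name='torso'>")
    torso = link_props("torso")

    n = sum(1 for name in links if name.startswith("vertebra_")
            and not name.endswith("_pitch_frame"))
    if n < 1:
        raise UrdfParseError("document has no vertebra links")
    geoms = [link_props(f"vertebra_{i}") for i in range(n)]
    lengths = [g.length for g in geoms]
    total_mass = sum(g.mass for g in geoms)

    # per-DOF limits from the first actuated joint
    joint = next(
        (j for j in robot.findall("joint") if j.get("name") == "tail_0_pitch"),
        None,
    )
    if joint is None:
        raise UrdfParseError("document has no <joint name='tail_0_pitch'>")
    limit = _req(joint, "limit", "tail_0_pitch")
    jl = JointLimits(
        position_range=(float(limit.get("lower")), float(limit.get("upper"))),
        velocity_range=(-float(limit.get("velocity")), float(limit.get("velocity"))),
        torque_range=(-float(limit.get("effort")), float(limit.get("effort"))),
    )

    base = params or DEFAULT_PARAMS
    tail = TailDesign(
        lengths=tuple(lengths),
        total_length=float(sum(lengths)),
        total_mass=float(total_mass),
        cross_section=geoms[0].width,
        min_length=base.min_vertebra_length,
    )
    import dataclasses as _dc
    eff_params = _dc.replace(
        base,
        torso_mass=torso.mass,
        torso_width=torso.width,
        torso_length=torso.length,
        torso_height=torso.height,
        tail_total_mass=tail.total_mass,
        tail_total_length=tail.total_length,
        tail_cross_section=tail.cross_section,
        joint_position_limit=jl.position_range[1],
        joint_velocity_limit=jl.velocity_range[1],
        joint_torque_limit=jl.torque_range[1],
    )
    return ModelSpec(torso=torso, tail=tail, joint_limits=jl, params=eff_params)
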