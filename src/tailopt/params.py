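"""Default physical parameters of the torso + tail models.

All values describe the reference animal-scale model used throughout:
a 5 kg torso (0.3 x 1.0 x 0.3 m square prism, long axis y) carrying a
1.5 kg, 1.5 m tail of square cross-section 0.1 x 0.1 m, articulated by
2-DOF (pitch + yaw) joints with +/-60 deg range, +/-360 deg/s velocity
and +/-5 Nm torque per DOF.  The torso:tail mass and length ratios match
highly manoeuvrable animals.
"""

from __future__ import annotations

import dataclasses
import math

DEG = math.pi / 180.0

#: Shared control-effort cap E (N^2 m^2): the single-vertebra tail has one
#: 2-DOF joint at +/-5 Nm per DOF, so its maximum possible u^T u is
#: 2 * 5^2 = 50.  Capping every design at this value equalises the total
#: actuation budget across morphologies.
EFFORT_CAP = 50.0

#: Default bound on the rate of change of each joint torque (Nm/s).  The
#: full +/-5 Nm range can be traversed in 50 ms.
TORQUE_RATE_LIMIT = 200.0


@dataclasses.dataclass(frozen=True)
class TableParams:
    """Reference model parameters (masses in kg, lengths in m)."""

    torso_mass: float = 5.0
    torso_width: float = 0.3   # local x
    torso_length: float = 1.0  # local y, the long axis
    torso_height: float = 0.3  # local z
    tail_total_mass: float = 1.5
    tail_total_length: float = 1.5
    tail_cross_section: float = 0.1
    joint_position_limit: float = 60.0 * DEG       # rad
    joint_velocity_limit: float = 360.0 * DEG      # rad/s
    joint_torque_limit: float = 5.0                # Nm
    torso_angle_limit: float = 180.0 * DEG         # rad
    torso_rate_limit: float = 360.0 * DEG          # rad/s
    effort_cap: float = EFFORT_CAP                 # N^2 m^2
    torque_rate_limit: float = TORQUE_RATE_LIMIT   # Nm/s
    min_vertebra_length: float = 0.2               # m, co-design lower bound

    # collision over-approximation (a declared artifact choice, see docs)
    torso_sphere_count: int = 3
    torso_sphere_radius: float = 0.25
    tail_sphere_radius: float = 0.07


DEFAULT_PARAMS = TableParams()
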