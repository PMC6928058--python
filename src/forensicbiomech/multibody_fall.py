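"""Planar 9-segment multibody fall-over-a-wall simulator.

The mannequin from :mod:`forensicbiomech.anthropometry` becomes an
articulated planar linkage: nine rigid links (head+neck+trunk and left/
right upper arm, forearm+hand, thigh, lower leg+foot) joined by eight pin
joints (shoulders, elbows, hips, knees), each joint carrying a torsional
spring and damper that stand in for passive muscular resistance.  The
default joint constants are 0.1 N m/deg springs (0.5 N m/deg at the hips)
and 0.001 N m s/deg dampers.  The linkage falls under gravity over a wall
and impacts the terrain with Newton restitution (0.5 against the wall,
0.2 against the ground) and Coulomb friction.

Although the three scenarios of interest are sagittal-plane motions, real
shoulders are ball joints; modelling them as in-plane pins removes
out-of-plane parameters that the planar classification targets (trunk
rotation, head-to-wall distance, face orientation) do not depend on.

Scenarios are labelled by heading:

- ``toward-wall-facing-wall``   walking on the upper road into the wall,
  face first;
- ``toward-wall-back-first``    walking backwards into the wall;
- ``on-wall-back-to-void``      walking along the wall top, back toward
  the drop, stepping off the far edge.

The simulation starts at the instant of wall contact (or edge departure),
standing upright with every joint at its rest angle and the whole body
translating at the stated walking speed.  Trunk orientation is reported as
the unwrapped cumulative rotation from upright, positive in the direction
the person faces (forward), so values beyond +/-180 deg are meaningful.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _planar
from ._planar import Box, ContactSettings, PlanarLinkage, Quadrant, StepSettings, Terrain
from .anthropometry import Mannequin
from .errors import DomainError, MissingMassError, NotTerminatedError
from .rigid_fall import RigidBodySpec

__all__ = [
    "JOINT_NAMES",
    "HEADINGS",
    "JointProperties",
    "ArticulatedMannequin",
    "ContactProperties",
    "Environment",
    "SimulationConfig",
    "InitialCondition",
    "TrajectoryRecord",
    "FallOutcome",
    "SpeedSweepResult",
    "build_articulated_mannequin",
    "lock_joints",
    "simulate",
    "classify_outcome",
    "minimum_fall_speed",
]

#: The eight pin joints of the planar mannequin.
JOINT_NAMES = (
    "left_shoulder",
    "left_elbow",
    "left_hip",
    "left_knee",
    "right_shoulder",
    "right_elbow",
    "right_hip",
    "right_knee",
)

HEADINGS = ("toward-wall-facing-wall", "toward-wall-back-first", "on-wall-back-to-void")

#: Head+neck share of the compound head+neck+trunk segment length
#: ((13 + 5.2) / 47 of stature fractions) — locates the shoulder axis.
HEAD_NECK_FRACTION_OF_TRUNK = 18.2 / 47.0

DEG = math.pi / 180.0

#: Foot geometry as stature fractions: overall foot length 15.2% of stature
#: (standard anthropometric proportion), split 80% forward of the ankle
#: (toes) and 20% behind (heel).  The foot is rigid with the shank (the
#: lower-leg+foot compound segment) and contributes contact geometry only.
FOOT_LENGTH_FRACTION = 0.152
FOOT_TOE_SHARE = 0.8

#: Anatomical joint ranges (degrees): (flexion limit, extension limit) and
#: the sign of the flexion direction in joint-coordinate terms for a person
#: facing +x (mirrored for a person facing -x).  Flexion of the shoulder,
#: elbow and hip swings the distal link toward the face; knee flexion swings
#: the shank backwards.
_JOINT_RANGES = {
    "shoulder": (180.0, 60.0, +1),
    "elbow": (150.0, 5.0, +1),
    "hip": (120.0, 15.0, +1),
    "knee": (150.0, 5.0, -1),
}


@dataclass(frozen=True)
class JointProperties:
    """Torsional joint: spring (N m/deg), damper (N m s/deg), rest angle (deg).

    The per-degree units follow common engineering usage for joint stiffness
    tables; they are converted to per-radian internally.
    """

    spring_constant: float = 0.1
    damper_constant: float = 0.001
    rest_angle: float = 0.0

    def __post_init__(self):
        if self.spring_constant < 0 or self.damper_constant < 0:
            raise DomainError("spring and damper constants must be non-negative")


@dataclass(frozen=True)
class ContactProperties:
    """Restitution per surface class plus Coulomb friction.

    ``friction_coefficient`` applies to the ground surfaces (road/lower
    ground); ``friction_wall`` to the wall faces and top, defaulting to the
    ground value when ``None``.
    """

    restitution_wall: float = 0.5
    restitution_ground: float = 0.2
    friction_coefficient: float = 0.8
    friction_wall: float | None = 0.2

    def __post_init__(self):
        if not (0 <= self.restitution_wall <= 1 and 0 <= self.restitution_ground <= 1):
            raise DomainError("restitution coefficients must lie in [0, 1]")
        if self.friction_coefficient < 0 or (
            self.friction_wall is not None and self.friction_wall < 0
        ):
            raise DomainError("friction coefficients must be non-negative")


@dataclass(frozen=True)
class Environment:
    """Wall-and-drop terrain, in a frame with the wall's road-side face at
    x = 0 and the upper road surface at y = 0.

    ``wall_height`` is the wall top above the upper road; ``drop`` is the
    fall from the wall top down to the lower ground beyond the wall.

    The default geometry (0.95 m high, 0.30 m thick parapet) is the
    reconstruction under which the documented outcomes of the three
    walking scenarios are reproduced simultaneously; see the methods
    notes for the calibration.
    """

    wall_height: float = 0.95
    wall_thickness: float = 0.3
    drop: float = 3.0

    def __post_init__(self):
        if self.wall_height <= 0 or self.wall_thickness <= 0:
            raise DomainError("wall dimensions must be positive")
        if self.drop <= self.wall_height:
            raise DomainError("the lower ground must lie below the upper road")

    @property
    def lower_ground_y(self) -> float:
        return self.wall_height - self.drop

    def terrain(self) -> Terrain:
        return Terrain(
            solids=[
                Quadrant("upper_road", "ground", x0=0.0, y0=0.0, sx=1),
                Box("wall", "wall", 0.0, self.wall_thickness, self.lower_ground_y, self.wall_height),
                Quadrant("lower_ground", "ground", x0=self.wall_thickness, y0=self.lower_ground_y, sx=-1),
            ]
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator and termination settings.

    Fixed-step Kutta–Merson at ``step`` seconds by default; ``adaptive``
    switches the smooth phases to embedded-error step control.  Motion
    terminates when kinetic energy stays below ``ke_threshold`` for
    ``quiet_time`` seconds, or at ``max_time``.  ``seed`` is carried for
    randomized sweeps only — a single simulation is deterministic.
    """

    step: float = 0.01
    max_time: float = 10.0
    adaptive: bool = False
    adaptive_tol: float = 1e-6
    ke_threshold: float = 0.1
    quiet_time: float = 0.5
    gravity: float = 9.81
    locked_joints: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.step <= 0 or self.max_time <= 0:
            raise DomainError("step and max_time must be positive")


@dataclass(frozen=True)
class InitialCondition:
    """Scenario entry state: heading label and walking (impact) speed."""

    heading: str
    speed: float

    def __post_init__(self):
        if self.heading not in HEADINGS:
            raise DomainError(f"unknown heading {self.heading!r}; expected one of {HEADINGS}")
        if not 0 <= self.speed <= 5:
            raise DomainError("initial speed must lie in [0, 5] m/s")

    @property
    def facing(self) -> int:
        """+1 when the person faces +x (the wall side), -1 otherwise."""
        return +1 if self.heading == "toward-wall-facing-wall" else -1


@dataclass(frozen=True)
class ArticulatedMannequin:
    """A mass-bearing mannequin plus its joint spring/damper properties."""

    mannequin: Mannequin
    joints: dict[str, JointProperties]
    contact_radius: float = 0.03
    #: joint-range stop stiffness (N m/deg) and damping (N m s/deg); the
    #: stops engage one-sidedly beyond the anatomical flexion/extension
    #: ranges.  Zero disables the stops.
    limit_stiffness: float = 5.0
    limit_damping: float = 0.05

    def __post_init__(self):
        missing = set(JOINT_NAMES) - set(self.joints)
        if missing:
            raise DomainError(f"missing joint properties: {sorted(missing)}")

    @property
    def n_links(self) -> int:
        return 9

    @property
    def n_joints(self) -> int:
        return 8


def build_articulated_mannequin(
    mannequin: Mannequin,
    joint_defaults: dict[str, JointProperties] | None = None,
    contact_radius: float = 0.03,
    limit_stiffness: float = 5.0,
    limit_damping: float = 0.05,
) -> ArticulatedMannequin:
    """Attach joint springs/dampers to a mass-bearing mannequin.

    Defaults: 0.5 N m/deg springs at the hips, 0.1 N m/deg elsewhere,
    0.001 N m s/deg dampers everywhere, rest angles at the initial standing
    posture (joints unloaded at start).  Entries in ``joint_defaults``
    override individual joints.
    """
    if not mannequin.has_masses:
        raise MissingMassError(
            "multibody simulation requires a mass-bearing mannequin "
            "(build with total_mass and a mass-bearing table)"
        )
    joints: dict[str, JointProperties] = {}
    for name in JOINT_NAMES:
        if name.endswith("hip"):
            joints[name] = JointProperties(spring_constant=0.5)
        else:
            joints[name] = JointProperties(spring_constant=0.1)
    if joint_defaults:
        joints.update(joint_defaults)
    return ArticulatedMannequin(
        mannequin=mannequin,
        joints=joints,
        contact_radius=contact_radius,
        limit_stiffness=limit_stiffness,
        limit_damping=limit_damping,
    )


# ---------------------------------------------------------------------------
# linkage construction

# generalized coordinates: [x, y, theta0, Lsh, Lel, Lhip, Lknee, Rsh, Rel, Rhip, Rknee]
_JOINT_COORD = {
    "left_shoulder": 3,
    "left_elbow": 4,
    "left_hip": 5,
    "left_knee": 6,
    "right_shoulder": 7,
    "right_elbow": 8,
    "right_hip": 9,
    "right_knee": 10,
}
_NQ = 11
_UP = math.pi / 2
_DOWN = -math.pi / 2


def _foot_extents(stature: float) -> tuple[float, float]:
    """(toe, heel) horizontal extents from the ankle, metres."""
    foot = FOOT_LENGTH_FRACTION * stature
    return FOOT_TOE_SHARE * foot, (1.0 - FOOT_TOE_SHARE) * foot


def _linkage_from(am: ArticulatedMannequin, gravity: float, facing: int = 1) -> PlanarLinkage:
    m = am.mannequin
    r = am.contact_radius
    trunk = m.segment("head_neck_trunk")
    lt = trunk.length
    d_sh = lt / 2 - HEAD_NECK_FRACTION_OF_TRUNK * lt  # shoulder above trunk CoM

    # foot plate: off-axis contact spheres at the distal shank end; toes
    # point in the facing direction (+perp of a downward link is +x)
    toe, heel = _foot_extents(m.stature)
    n_toe = max(2, int(math.ceil(toe / 0.07)))
    foot_offsets = [facing * d for d in np.linspace(toe / n_toe, toe, n_toe)]
    foot_offsets.append(-facing * heel)

    links = [
        _planar.LinkSpec(
            name="head_neck_trunk",
            mass=trunk.mass,
            inertia=trunk.inertia_com,
            length=lt,
            terms=[],
            ang_indices=(2,),
            ang_offset=_UP,
            s_bounds=(-lt / 2, lt / 2),
            radius=r,
        )
    ]
    for side in ("left", "right"):
        jsh = _JOINT_COORD[f"{side}_shoulder"]
        jel = _JOINT_COORD[f"{side}_elbow"]
        jhip = _JOINT_COORD[f"{side}_hip"]
        jkn = _JOINT_COORD[f"{side}_knee"]
        ua = m.segment(f"{side}_upper_arm")
        fa = m.segment(f"{side}_forearm_hand")
        th = m.segment(f"{side}_thigh")
        ll = m.segment(f"{side}_lower_leg_foot")
        links += [
            _planar.LinkSpec(
                name=f"{side}_upper_arm",
                mass=ua.mass,
                inertia=ua.inertia_com,
                length=ua.length,
                terms=[(d_sh, _UP, (2,)), (ua.length / 2, _DOWN, (2, jsh))],
                ang_indices=(2, jsh),
                ang_offset=_DOWN,
                s_bounds=(-ua.length / 2, ua.length / 2),
                radius=r,
            ),
            _planar.LinkSpec(
                name=f"{side}_forearm_hand",
                mass=fa.mass,
                inertia=fa.inertia_com,
                length=fa.length,
                terms=[
                    (d_sh, _UP, (2,)),
                    (ua.length, _DOWN, (2, jsh)),
                    (fa.length / 2, _DOWN, (2, jsh, jel)),
                ],
                ang_indices=(2, jsh, jel),
                ang_offset=_DOWN,
                s_bounds=(-fa.length / 2, fa.length / 2),
                radius=r,
            ),
            _planar.LinkSpec(
                name=f"{side}_thigh",
                mass=th.mass,
                inertia=th.inertia_com,
                length=th.length,
                terms=[(lt / 2, _DOWN, (2,)), (th.length / 2, _DOWN, (2, jhip))],
                ang_indices=(2, jhip),
                ang_offset=_DOWN,
                s_bounds=(-th.length / 2, th.length / 2),
                radius=r,
            ),
            _planar.LinkSpec(
                name=f"{side}_lower_leg_foot",
                mass=ll.mass,
                inertia=ll.inertia_com,
                length=ll.length,
                terms=[
                    (lt / 2, _DOWN, (2,)),
                    (th.length, _DOWN, (2, jhip)),
                    (ll.length / 2, _DOWN, (2, jhip, jkn)),
                ],
                ang_indices=(2, jhip, jkn),
                ang_offset=_DOWN,
                s_bounds=(-ll.length / 2, ll.length / 2),
                radius=r,
                extra_samples=tuple((ll.length / 2, b) for b in foot_offsets),
            ),
        ]

    spring = np.zeros(_NQ)
    damper = np.zeros(_NQ)
    rest = np.zeros(_NQ)
    lo = np.full(_NQ, -np.inf)
    hi = np.full(_NQ, np.inf)
    lim_k = np.zeros(_NQ)
    lim_c = np.zeros(_NQ)
    for name, j in _JOINT_COORD.items():
        props = am.joints[name]
        # stored per degree, applied per radian
        spring[j] = props.spring_constant / DEG
        damper[j] = props.damper_constant / DEG
        rest[j] = props.rest_angle * DEG
        if am.limit_stiffness > 0:
            flex, ext, sign = _JOINT_RANGES[name.split("_", 1)[1]]
            # mirror the flexion direction for a person facing -x
            if sign * facing > 0:
                lo[j], hi[j] = -ext * DEG, flex * DEG
            else:
                lo[j], hi[j] = -flex * DEG, ext * DEG
            lim_k[j] = am.limit_stiffness / DEG
            lim_c[j] = am.limit_damping / DEG

    return PlanarLinkage(
        links=links,
        nq=_NQ,
        free_base=True,
        gravity=gravity,
        spring=spring,
        damper=damper,
        rest=rest,
        limit_lo=lo,
        limit_hi=hi,
        limit_spring=lim_k,
        limit_damper=lim_c,
    )


def lock_joints(am: ArticulatedMannequin) -> RigidBodySpec:
    """Equivalent single rigid body of the straightened mannequin.

    Total mass, composite CoM location along the standing body axis, and the
    composite central inertia obtained by parallel-axis summation of the
    link inertias in the upright posture.  ``b`` is the CoM-to-lower-end
    (foot) distance — the lever arm of an end impact.
    """
    linkage = _linkage_from(am, gravity=0.0)
    q0 = np.zeros(_NQ)
    coms = linkage.com_positions(q0)  # trunk CoM at the origin
    masses = linkage.masses
    total = float(masses.sum())
    com_y = float(np.dot(masses, coms[:, 1]) / total)
    inertia = float(
        np.sum(linkage.inertias)
        + np.sum(masses * np.sum((coms - [0.0, com_y]) ** 2, axis=1))
    )
    m = am.mannequin
    trunk = m.segment("head_neck_trunk")
    leg = m.segment("left_thigh").length + m.segment("left_lower_leg_foot").length
    foot_y = -(trunk.length / 2 + leg)  # lower body end, trunk CoM frame
    length = m.stature
    b = com_y - foot_y
    return RigidBodySpec(m=total, l=length, b=b, I=inertia)


def _locked_linkage(am: ArticulatedMannequin, gravity: float) -> tuple[PlanarLinkage, float]:
    """Single-link linkage of the composite rigid body.

    Returns the linkage and the CoM height above the lower (foot) end."""
    body = lock_joints(am)
    link = _planar.LinkSpec(
        name="locked_body",
        mass=body.m,
        inertia=body.I,
        length=body.l,
        terms=[],
        ang_indices=(2,),
        ang_offset=_UP,
        # the CoM sits b above the feet: samples span [-b, l - b]
        s_bounds=(-body.b, body.l - body.b),
        radius=am.contact_radius,
    )
    return (
        PlanarLinkage(links=[link], nq=3, free_base=True, gravity=gravity),
        body.b,
    )


# ---------------------------------------------------------------------------
# simulation


@dataclass
class TrajectoryRecord:
    """Sampled fall trajectory plus scenario metadata.

    ``trunk_rotation_deg`` is the unwrapped cumulative trunk rotation from
    upright, positive in the person's forward (facing) direction.
    """

    times: np.ndarray
    link_names: tuple[str, ...]
    link_poses: np.ndarray  # (T, nl, 3): x, y, angle
    link_velocities: np.ndarray  # (T, nl, 3)
    com: np.ndarray  # (T, 2)
    kinetic_energy: np.ndarray
    trunk_rotation_deg: np.ndarray  # (T,)
    head_position: np.ndarray  # (T, 2)
    events: list
    energy_audit: list
    terminated: bool
    heading: str
    facing: int
    environment: Environment
    q: np.ndarray
    qdot: np.ndarray

    def to_csv(self, path) -> None:
        """Write time plus per-link (x, y, angle) columns."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["time_s"]
            for name in self.link_names:
                header += [f"{name}_x_m", f"{name}_y_m", f"{name}_angle_rad"]
            w.writerow(header)
            for k in range(len(self.times)):
                row = [f"{self.times[k]:.4f}"]
                for i in range(len(self.link_names)):
                    row += [f"{v:.6f}" for v in self.link_poses[k, i]]
                w.writerow(row)


def _initial_state(
    am: ArticulatedMannequin,
    environment: Environment,
    initial: InitialCondition,
    locked: bool,
    com_height_locked: float | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Standing posture at the instant of wall contact / edge departure."""
    m = am.mannequin
    r = am.contact_radius
    trunk_l = m.segment("head_neck_trunk").length
    leg = m.segment("left_thigh").length + m.segment("left_lower_leg_foot").length

    toe, heel = _foot_extents(m.stature)
    if locked:
        toe = heel = 0.0  # the composite body has no foot plate
    # horizontal extent of the foot toward the wall: toes lead when facing
    # it, heel leads when walking backwards into it
    lead = toe if initial.facing > 0 else heel
    if initial.heading == "on-wall-back-to-void":
        ground_y = environment.wall_height
        x0 = environment.wall_thickness - r  # heel overhangs the far edge
    else:
        ground_y = 0.0
        x0 = -r - lead  # leading foot sphere touching the road-side face

    if locked:
        nq = 3
        y0 = ground_y + r + com_height_locked
    else:
        nq = _NQ
        y0 = ground_y + r + leg + trunk_l / 2
    q0 = np.zeros(nq)
    q0[0], q0[1] = x0, y0
    v0 = np.zeros(nq)
    v0[0] = initial.speed
    return q0, v0, initial.facing


def simulate(
    mannequin: ArticulatedMannequin,
    environment: Environment | None,
    contact: ContactProperties,
    initial: InitialCondition,
    config: SimulationConfig = SimulationConfig(),
) -> TrajectoryRecord:
    """Integrate the fall and return the sampled trajectory.

    ``environment=None`` disables all contact (free flight) — useful for
    conservation checks.  ``config.locked_joints=True`` replaces the
    articulated mannequin by its rigid composite (see :func:`lock_joints`)
    for cross-validation against the closed-form impact model.
    """
    if config.locked_joints:
        linkage, com_h = _locked_linkage(mannequin, config.gravity)
    else:
        linkage, com_h = _linkage_from(mannequin, config.gravity, initial.facing), None

    q0, v0, facing = _initial_state(
        mannequin, environment or Environment(), initial, config.locked_joints, com_h
    )

    terrain = environment.terrain() if environment is not None else None
    mu_wall = (
        contact.friction_wall
        if contact.friction_wall is not None
        else contact.friction_coefficient
    )
    settings = ContactSettings(
        restitution={"wall": contact.restitution_wall, "ground": contact.restitution_ground},
        friction={"wall": mu_wall, "ground": contact.friction_coefficient},
    )
    raw = _planar.simulate_linkage(
        linkage,
        terrain,
        settings if terrain is not None else None,
        q0,
        v0,
        StepSettings(
            step=config.step,
            max_time=config.max_time,
            ke_threshold=config.ke_threshold,
            quiet_time=config.quiet_time,
            adaptive=config.adaptive,
            adaptive_tol=config.adaptive_tol,
        ),
    )

    # trunk (or locked body) is link 0; theta0 is coordinate 2, naturally unwrapped
    dtheta = np.degrees(raw.q[:, 2] - raw.q[0, 2])
    trunk_rot = -facing * dtheta

    trunk_len = linkage.links[0].length
    if config.locked_joints:
        head_arm = linkage.links[0].s_bounds[1]
    else:
        head_arm = trunk_len / 2
    angles = raw.link_poses[:, 0, 2]
    head = raw.link_poses[:, 0, :2] + head_arm * np.column_stack(
        [np.cos(angles), np.sin(angles)]
    )

    return TrajectoryRecord(
        times=raw.times,
        link_names=tuple(l.name for l in linkage.links),
        link_poses=raw.link_poses,
        link_velocities=raw.link_velocities,
        com=raw.com,
        kinetic_energy=raw.kinetic_energy,
        trunk_rotation_deg=trunk_rot,
        head_position=head,
        events=raw.events,
        energy_audit=raw.energy_audit,
        terminated=raw.terminated,
        heading=initial.heading,
        facing=facing,
        environment=environment if environment is not None else Environment(),
        q=raw.q,
        qdot=raw.qdot,
    )


# ---------------------------------------------------------------------------
# outcome classification


@dataclass(frozen=True)
class FallOutcome:
    """End-state classification of a fall trajectory.

    ``final_trunk_orientation`` is the unwrapped trunk rotation in degrees,
    positive forward (toward the face), negative backward.  ``face_up`` is
    ``None`` when the body ends near upright and the notion does not apply.
    """

    fell: bool
    final_trunk_orientation: float
    head_to_wall_distance: float
    face_up: bool | None

    #: horizontal head-to-wall distance below which the head counts as
    #: "near" the wall (about half a body height)
    NEAR_WALL_THRESHOLD = 1.0

    @property
    def head_near_wall(self) -> bool:
        return self.head_to_wall_distance < self.NEAR_WALL_THRESHOLD


def classify_outcome(trajectory: TrajectoryRecord, environment: Environment | None = None) -> FallOutcome:
    """Classify a terminated trajectory.

    Raises :class:`NotTerminatedError` if the motion never became quiescent.
    """
    if not trajectory.terminated:
        raise NotTerminatedError(
            "trajectory did not reach quiescence; increase max_time or inspect the motion"
        )
    env = environment or trajectory.environment
    rot = float(trajectory.trunk_rotation_deg[-1])
    com = trajectory.com[-1]
    fell = bool(com[0] > 0 and com[1] < env.lower_ground_y + 1.2)

    head = trajectory.head_position[-1]
    if head[0] < 0:
        dist = -head[0]
    elif head[0] > env.wall_thickness:
        dist = head[0] - env.wall_thickness
    else:
        dist = 0.0

    # face orientation from the unwrapped forward-positive rotation
    mod = rot % 360.0
    upright = min(mod, 360.0 - mod) < 45.0
    face_up: bool | None
    if upright:
        face_up = None
    else:
        face_up = mod > 180.0

    return FallOutcome(
        fell=fell,
        final_trunk_orientation=rot,
        head_to_wall_distance=float(dist),
        face_up=face_up,
    )


@dataclass
class SpeedSweepResult:
    """Result of a minimum-fall-speed search over a speed grid."""

    minimum_speed: float | None
    outcomes: dict[float, FallOutcome]
    failures: dict[float, str]


def minimum_fall_speed(
    mannequin: ArticulatedMannequin,
    environment: Environment,
    contact: ContactProperties,
    heading: str,
    speeds=(0.5, 1.0, 1.5, 2.0),
    config: SimulationConfig = SimulationConfig(),
) -> SpeedSweepResult:
    """Smallest grid speed at which the person falls over the wall.

    Simulates each speed in ascending order; simulation failures are
    recorded per grid point rather than raised."""
    speeds = sorted(speeds)
    if any(s2 <= s1 for s1, s2 in zip(speeds, speeds[1:])):
        raise DomainError("speed grid must be strictly increasing")
    outcomes: dict[float, FallOutcome] = {}
    failures: dict[float, str] = {}
    minimum = None
    for s in speeds:
        try:
            traj = simulate(mannequin, environment, contact, InitialCondition(heading, s), config)
            out = classify_outcome(traj, environment)
        except Exception as exc:  # noqa: BLE001 - reported per grid point
            failures[s] = f"{type(exc).__name__}: {exc}"
            continue
        outcomes[s] = out
        if out.fell and minimum is None:
            minimum = s
    return SpeedSweepResult(minimum_speed=minimum, outcomes=outcomes, failures=failures)
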