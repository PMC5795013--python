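"""Articulated ant body: morphometry, kinematics, and the physics backend.

The body is a hierarchy of rigid segments taken from morphometric tables of
a desert ant (Cataglyphis): three trunk boxes (head, thorax, abdomen) and six
legs, each a chain of capsules (coxa, femur, tibia, tarsus) with a uniform
0.2 mm radius.  Each leg is actuated at three degrees of freedom — the
body-coxa joint (protraction/retraction about the vertical axis), the
trochanter-femur joint (levation/depression) and the femur-tibia joint
(flexion/extension) — giving 18 actuated DOF in total.  Each joint is driven
by an antagonistic muscle pair acting through fixed moment arms.

Working units are millimetres, milligrams, millinewtons and seconds, which
form a consistent system in which gravity is 9810 mm/s^2 (1 mN / 1 mg =
10^6 mm/s^2).  No unit rescaling is needed at the backend boundary because
the reduced backend has no contact solver to upset.

The physics backend is a contract (:class:`PhysicsBackend`) plus one
implementation, :class:`ReducedBackend`: the trunk is a single rigid body,
stance legs transmit their joint torques to the ground through the
transpose-inverse of the leg Jacobian (massless force transmission), vertical
support is a damped-strut model driven by the ratio of transmitted vertical
force to body weight, and yaw follows a first-order turning law in which the
body pivots toward the side with the greater propulsive stance impulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Morphometry",
    "SegmentSpec",
    "LegGeometry",
    "MuscleAttachment",
    "BodyModel",
    "BodyState",
    "PhysicsBackend",
    "ReducedBackend",
    "ConfigurationError",
    "ReachError",
    "build_body",
    "mass_proportions",
    "joint_torque_from_muscles",
    "muscle_kinematics",
    "leg_foot_position",
    "leg_jacobian",
    "leg_ik",
    "torques_from_ground_force",
    "LEG_NAMES",
    "LEG_POSITIONS",
    "JOINT_NAMES",
    "TRIPOD_A",
]

# gravity in mm/s^2
GRAVITY_MM_S2 = 9810.0

LEG_POSITIONS = ("front", "middle", "back")
JOINT_NAMES = ("body_coxa", "coxa_femur", "femur_tibia")
# leg ordering used everywhere: all left legs front-to-back, then right
LEG_NAMES = ("LF", "LM", "LB", "RF", "RM", "RB")
# tripod A = legs sharing phase 0 (left front, right middle, left back)
TRIPOD_A = ("LF", "RM", "LB")

#: uniform leg-capsule radius (mm)
LEG_RADIUS_MM = 0.2

# leg segment lengths (mm): position -> (coxa, femur, tibia, tarsus)
DEFAULT_LEG_LENGTHS = {
    "front": (0.25, 2.49, 2.33, 2.37),
    "middle": (0.25, 2.82, 2.74, 3.13),
    "back": (0.25, 3.48, 3.40, 3.80),
}
# trunk boxes: name -> (dimensions xyz in mm, mass in mg)
DEFAULT_TRUNK = {
    "head": ((2.67, 2.20, 0.50), 5.23),
    "thorax": ((3.07, 1.01, 0.50), 3.87),
    "abdomen": ((3.43, 2.46, 0.50), 11.35),
}
# lumped mass of a single leg (mg); table proportions count left/right pairs
DEFAULT_LEG_MASSES = {"front": 0.60, "middle": 0.50, "back": 0.70}

# leg-root placement on the thorax (mm) and neutral splay angle (deg,
# measured from the body +x axis toward the leg's own side)
ROOT_X_MM = {"front": 1.2, "middle": 0.0, "back": -1.2}
ROOT_Y_MM = 0.5
NEUTRAL_SPLAY_DEG = {"front": 50.0, "middle": 90.0, "back": 130.0}

#: default standing posture: radial foot distance from the leg root and
#: body-centre height above ground (mm)
DEFAULT_STANCE_RADIUS_MM = 4.0
DEFAULT_STANDING_HEIGHT_MM = 1.8

# default joint-limit half-widths about the rest angle (deg)
JOINT_HALF_WIDTH_DEG = (60.0, 60.0, 75.0)

DEFAULT_MOMENT_ARM_MM = 0.2
DEFAULT_ANGLE_TO_LENGTH_GAIN = 0.5  # normalised length per rad


class ConfigurationError(ValueError):
    """Missing or non-positive morphometry / inconsistent model wiring."""


class ReachError(ValueError):
    """An inverse-kinematics target lies outside the leg workspace."""


@dataclass(frozen=True)
class Morphometry:
    """The measured segment table: leg lengths, trunk boxes, leg masses."""

    leg_lengths: dict = field(default_factory=lambda: dict(DEFAULT_LEG_LENGTHS))
    trunk: dict = field(default_factory=lambda: dict(DEFAULT_TRUNK))
    leg_masses: dict = field(default_factory=lambda: dict(DEFAULT_LEG_MASSES))

    def validate(self) -> None:
        for pos in LEG_POSITIONS:
            if pos not in self.leg_lengths:
                raise ConfigurationError(f"missing leg-length row for {pos!r}")
            if pos not in self.leg_masses:
                raise ConfigurationError(f"missing leg mass for {pos!r}")
            if any(v <= 0 for v in self.leg_lengths[pos]) or self.leg_masses[pos] <= 0:
                raise ConfigurationError(f"non-positive morphometry for {pos!r} leg")
        for name in ("head", "thorax", "abdomen"):
            if name not in self.trunk:
                raise ConfigurationError(f"missing trunk segment {name!r}")
            dims, mass = self.trunk[name]
            if any(v <= 0 for v in dims) or mass <= 0:
                raise ConfigurationError(f"non-positive morphometry for {name!r}")

    @classmethod
    def from_csv(cls, leg_lengths_csv, masses_csv) -> "Morphometry":
        """Load the two tables.

        ``leg_lengths_csv`` columns: position, coxa, femur, tibia, tarsus.
        ``masses_csv`` columns: segment, dim_x, dim_y, dim_z, mass.
        """
        lengths = pd.read_csv(leg_lengths_csv, comment="#")
        masses = pd.read_csv(masses_csv, comment="#")
        leg_lengths = {
            str(row["position"]).lower(): (
                float(row["coxa"]),
                float(row["femur"]),
                float(row["tibia"]),
                float(row["tarsus"]),
            )
            for _, row in lengths.iterrows()
        }
        trunk, leg_masses = {}, {}
        for _, row in masses.iterrows():
            seg = str(row["segment"]).lower()
            if seg.endswith("leg"):
                leg_masses[seg.split()[0].replace("_leg", "")] = float(row["mass"])
            else:
                trunk[seg] = (
                    (float(row["dim_x"]), float(row["dim_y"]), float(row["dim_z"])),
                    float(row["mass"]),
                )
        morpho = cls(leg_lengths=leg_lengths, trunk=trunk, leg_masses=leg_masses)
        morpho.validate()
        return morpho


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    kind: str  # "box" or "capsule"
    dims_mm: tuple
    mass_mg: float


@dataclass(frozen=True)
class LegGeometry:
    """One leg: side, position, segment lengths, root pose in the body frame."""

    name: str  # e.g. "LF"
    side: int  # +1 left, -1 right
    position: str  # front / middle / back
    coxa: float
    femur: float
    tibia: float
    tarsus: float
    mass_mg: float
    root: tuple  # (x, y, z) mm in body frame
    splay_rad: float  # neutral outward direction from body +x, own side

    @property
    def distal(self) -> float:
        """Effective distal link: tibia plus half the tarsus.

        The compliant tarsus drags rather than acting as a rigid extension,
        so the ground contact point is taken at mid-tarsus; this also keeps
        the two-link workspace annulus wide enough for the stride excursions
        of the long-femured back legs.
        """
        return self.tibia + 0.5 * self.tarsus


@dataclass(frozen=True)
class MuscleAttachment:
    """Antagonistic-pair geometry at one joint.

    ``q_rest`` is the joint angle at which both muscles sit at rest length
    (L_ce = 1); ``gain`` converts joint rotation into normalised fibre
    length, with opposite signs for the two muscles of the pair.
    """

    leg: int
    joint: int
    arm_agonist_mm: float = DEFAULT_MOMENT_ARM_MM
    arm_antagonist_mm: float = DEFAULT_MOMENT_ARM_MM
    q_rest: float = 0.0
    gain: float = DEFAULT_ANGLE_TO_LENGTH_GAIN

    def __post_init__(self) -> None:
        if self.arm_agonist_mm <= 0 or self.arm_antagonist_mm <= 0:
            raise ValueError("moment arms must be positive")


@dataclass
class BodyModel:
    """The assembled articulated body."""

    trunk: dict  # name -> SegmentSpec
    legs: list  # 6 LegGeometry, LEG_NAMES order
    attachments: list  # 6 x 3 nested list of MuscleAttachment
    joint_half_width_rad: tuple
    stance_radius_mm: float = DEFAULT_STANCE_RADIUS_MM
    standing_height_mm: float = DEFAULT_STANDING_HEIGHT_MM

    @property
    def n_actuated_dof(self) -> int:
        return sum(3 for _ in self.legs)

    @property
    def total_mass_mg(self) -> float:
        return sum(s.mass_mg for s in self.trunk.values()) + sum(
            leg.mass_mg for leg in self.legs
        )

    def leg_index(self, name: str) -> int:
        return LEG_NAMES.index(name)

    def neutral_foot_position(self, leg_idx: int) -> np.ndarray:
        """Default stance foot point (body frame, mm): radially out from the
        root at the neutral splay angle, at standing depth below the body."""
        leg = self.legs[leg_idx]
        ang = leg.side * leg.splay_rad
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        p = np.asarray(leg.root) + self.stance_radius_mm * direction
        p[2] = -self.standing_height_mm
        return p

    def joint_limits(self, leg_idx: int, joint_idx: int) -> tuple[float, float]:
        att = self.attachments[leg_idx][joint_idx]
        hw = self.joint_half_width_rad[joint_idx]
        return att.q_rest - hw, att.q_rest + hw

    def mirrored(self) -> "BodyModel":
        """Reflect about the sagittal plane (an involution)."""
        order = [3, 4, 5, 0, 1, 2]  # swap left/right blocks
        legs = []
        for new_idx, old_idx in enumerate(order):
            leg = self.legs[old_idx]
            root = (leg.root[0], -leg.root[1], leg.root[2])
            legs.append(
                replace(leg, name=LEG_NAMES[new_idx], side=-leg.side, root=root)
            )
        atts = [
            [replace(a, leg=new_idx) for a in self.attachments[old_idx]]
            for new_idx, old_idx in enumerate(order)
        ]
        return replace(self, legs=legs, attachments=atts)

    # -- URDF-like YAML dialect ------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "trunk": {
                name: {"kind": s.kind, "dims_mm": list(s.dims_mm), "mass_mg": s.mass_mg}
                for name, s in self.trunk.items()
            },
            "legs": [
                {
                    "name": leg.name,
                    "side": int(leg.side),
                    "position": leg.position,
                    "lengths_mm": [
                        float(v) for v in (leg.coxa, leg.femur, leg.tibia, leg.tarsus)
                    ],
                    "mass_mg": float(leg.mass_mg),
                    "root_mm": [float(v) for v in leg.root],
                    "splay_rad": float(leg.splay_rad),
                }
                for leg in self.legs
            ],
            "joint_half_width_rad": [float(v) for v in self.joint_half_width_rad],
            "attachments": [
                [
                    {
                        "arm_agonist_mm": float(a.arm_agonist_mm),
                        "arm_antagonist_mm": float(a.arm_antagonist_mm),
                        "q_rest": float(a.q_rest),
                        "gain": float(a.gain),
                    }
                    for a in row
                ]
                for row in self.attachments
            ],
            "stance_radius_mm": float(self.stance_radius_mm),
            "standing_height_mm": float(self.standing_height_mm),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BodyModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        trunk = {
            name: SegmentSpec(name, s["kind"], tuple(s["dims_mm"]), s["mass_mg"])
            for name, s in doc["trunk"].items()
        }
        legs = [
            LegGeometry(
                name=d["name"],
                side=d["side"],
                position=d["position"],
                coxa=d["lengths_mm"][0],
                femur=d["lengths_mm"][1],
                tibia=d["lengths_mm"][2],
                tarsus=d["lengths_mm"][3],
                mass_mg=d["mass_mg"],
                root=tuple(d["root_mm"]),
                splay_rad=d["splay_rad"],
            )
            for d in doc["legs"]
        ]
        atts = [
            [
                MuscleAttachment(leg=i, joint=j, **doc["attachments"][i][j])
                for j in range(3)
            ]
            for i in range(6)
        ]
        return cls(
            trunk=trunk,
            legs=legs,
            attachments=atts,
            joint_half_width_rad=tuple(doc["joint_half_width_rad"]),
            stance_radius_mm=doc["stance_radius_mm"],
            standing_height_mm=doc["standing_height_mm"],
        )


# ---------------------------------------------------------------------------
# leg kinematics
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _maybe_njit(fn):
    return _njit(cache=True)(fn) if _HAVE_NUMBA else fn


@_maybe_njit
def _ik_kernel(side, splay, coxa, lf, lt, rx, ry, rz, px, py, pz, clamp):
    """Closed-form IK core; returns (ok, q1, q2, q3, rho, lo, hi)."""
    dx, dy, dz = px - rx, py - ry, pz - rz
    yaw = np.arctan2(dy, dx)
    q1 = side * ((yaw - side * splay + np.pi) % (2.0 * np.pi) - np.pi)
    r = np.hypot(dx, dy) - coxa
    z = dz
    rho2 = r * r + z * z
    lo = abs(lf - lt)
    hi = lf + lt
    rho = np.sqrt(rho2)
    if rho > hi or rho < lo:
        if not clamp:
            return False, 0.0, 0.0, 0.0, rho, lo, hi
        rho_c = rho
        if rho_c < lo * (1 + 1e-9) + 1e-12:
            rho_c = lo * (1 + 1e-9) + 1e-12
        if rho_c > hi * (1 - 1e-9):
            rho_c = hi * (1 - 1e-9)
        scale = rho_c / max(rho, 1e-12)
        r, z = r * scale, z * scale
        rho2 = r * r + z * z
    cos_q3 = (rho2 - lf * lf - lt * lt) / (2.0 * lf * lt)
    if cos_q3 > 1.0:
        cos_q3 = 1.0
    elif cos_q3 < -1.0:
        cos_q3 = -1.0
    q3 = -np.arccos(cos_q3)
    q2 = np.arctan2(z, r) - np.arctan2(lt * np.sin(q3), lf + lt * np.cos(q3))
    q2 = (q2 + np.pi) % (2.0 * np.pi) - np.pi
    return True, q1, q2, q3, rho, lo, hi


@_maybe_njit
def _solve3(m00, m01, m02, m10, m11, m12, m20, m21, m22, b0, b1, b2):
    """Cramer's-rule solve of a 3x3 system; returns (ok, x0, x1, x2)."""
    det = (
        m00 * (m11 * m22 - m12 * m21)
        - m01 * (m10 * m22 - m12 * m20)
        + m02 * (m10 * m21 - m11 * m20)
    )
    if abs(det) < 1e-300:
        return False, 0.0, 0.0, 0.0
    x0 = (
        b0 * (m11 * m22 - m12 * m21)
        - m01 * (b1 * m22 - m12 * b2)
        + m02 * (b1 * m21 - m11 * b2)
    ) / det
    x1 = (
        m00 * (b1 * m22 - m12 * b2)
        - b0 * (m10 * m22 - m12 * m20)
        + m02 * (m10 * b2 - b1 * m20)
    ) / det
    x2 = (
        m00 * (m11 * b2 - b1 * m21)
        - m01 * (m10 * b2 - b1 * m20)
        + b0 * (m10 * m21 - m11 * m20)
    ) / det
    return True, x0, x1, x2


def leg_foot_position(leg: LegGeometry, q: np.ndarray) -> np.ndarray:
    """Forward kinematics: foot (tarsus tip) in the body frame (mm).

    q = (q1 protraction, q2 levation, q3 flexion), all relative to the
    neutral splay / horizontal femur.  Equal joint angles on a left and a
    right leg give mirror-symmetric feet.
    """
    q1, q2, q3 = q
    phi = leg.side * (leg.splay_rad + q1)
    r_loc = leg.coxa + leg.femur * np.cos(q2) + leg.distal * np.cos(q2 + q3)
    z_loc = leg.femur * np.sin(q2) + leg.distal * np.sin(q2 + q3)
    return np.asarray(leg.root) + np.array(
        [r_loc * np.cos(phi), r_loc * np.sin(phi), z_loc]
    )


def leg_jacobian(leg: LegGeometry, q: np.ndarray) -> np.ndarray:
    """Analytic 3x3 Jacobian d(foot)/d(q) in mm/rad, body frame."""
    q1, q2, q3 = q
    phi = leg.side * (leg.splay_rad + q1)
    c, s = np.cos(phi), np.sin(phi)
    c23, s23 = np.cos(q2 + q3), np.sin(q2 + q3)
    r_loc = leg.coxa + leg.femur * np.cos(q2) + leg.distal * c23
    z_loc = leg.femur * np.sin(q2) + leg.distal * s23
    col1 = leg.side * np.array([-s * r_loc, c * r_loc, 0.0])
    col2 = np.array([-c * z_loc, -s * z_loc, r_loc - leg.coxa])
    col3 = np.array([-c * leg.distal * s23, -s * leg.distal * s23, leg.distal * c23])
    return np.column_stack([col1, col2, col3])


def leg_ik(leg: LegGeometry, p_body: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Closed-form inverse kinematics for the 3-DOF chain.

    Yaw from the horizontal bearing of the target; then planar two-link IK
    (femur + lumped tibia-tarsus) with the knee flexed downward.  Targets
    outside the annular workspace raise :class:`ReachError`, or are radially
    clamped onto its boundary when ``clamp`` is true.
    """
    p = np.asarray(p_body, dtype=float)
    ok, q1, q2, q3, rho, lo, hi = _ik_kernel(
        float(leg.side), float(leg.splay_rad), leg.coxa, leg.femur, leg.distal,
        leg.root[0], leg.root[1], leg.root[2], p[0], p[1], p[2], clamp,
    )
    if not ok:
        raise ReachError(
            f"foot target at {rho:.3f} mm from the {leg.name} knee root is "
            f"outside the reachable band [{lo:.3f}, {hi:.3f}] mm"
        )
    return np.array([q1, q2, q3])


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def torques_from_ground_force(
    leg: LegGeometry, q: np.ndarray, foot_force: np.ndarray
) -> np.ndarray:
    """Jacobian-transpose map of an end-effector force to joint torques.

    ``foot_force`` is the external force on the foot in the body frame (mN);
    the result is in mN*mm.  Near-singular configurations emit a warning but
    still return the torques.
    """
    jac = leg_jacobian(leg, q)
    cond = np.linalg.cond(jac)
    if not np.isfinite(cond) or cond > 1e8:
        warnings.warn(
            f"leg {leg.name} is near a kinematic singularity (cond={cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return jac.T @ np.asarray(foot_force, dtype=float)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def build_body(morphometry: Morphometry | None = None) -> BodyModel:
    """Assemble the body model from a morphometry table (defaults printed).

    Muscle rest angles are set from the default standing posture (the joint
    angles that place each foot at its neutral stance point), so joint-limit
    windows are centred on the working posture.
    """
    morpho = morphometry or Morphometry()
    morpho.validate()
    trunk = {
        name: SegmentSpec(name, "box", dims, mass)
        for name, (dims, mass) in morpho.trunk.items()
    }
    legs = []
    for name in LEG_NAMES:
        side = 1 if name[0] == "L" else -1
        position = {"F": "front", "M": "middle", "B": "back"}[name[1]]
        coxa, femur, tibia, tarsus = morpho.leg_lengths[position]
        legs.append(
            LegGeometry(
                name=name,
                side=side,
                position=position,
                coxa=coxa,
                femur=femur,
                tibia=tibia,
                tarsus=tarsus,
                mass_mg=morpho.leg_masses[position],
                root=(ROOT_X_MM[position], side * ROOT_Y_MM, 0.0),
                splay_rad=np.deg2rad(NEUTRAL_SPLAY_DEG[position]),
            )
        )
    body = BodyModel(
        trunk=trunk,
        legs=legs,
        attachments=[[MuscleAttachment(leg=i, joint=j) for j in range(3)] for i in range(6)],
        joint_half_width_rad=tuple(np.deg2rad(JOINT_HALF_WIDTH_DEG)),
    )
    # centre each joint's rest angle on the standing posture
    for i, leg in enumerate(body.legs):
        q_stand = leg_ik(leg, body.neutral_foot_position(i))
        body.attachments[i] = [
            MuscleAttachment(leg=i, joint=j, q_rest=float(q_stand[j]))
            for j in range(3)
        ]
    return body


def mass_proportions(body: BodyModel) -> dict:
    """Per-segment share of total body mass (%), legs reported as pairs."""
    total = body.total_mass_mg
    if total <= 0:
        raise ValueError("total mass must be positive")
    out = {name: s.mass_mg / total * 100.0 for name, s in body.trunk.items()}
    for position in LEG_POSITIONS:
        pair = sum(leg.mass_mg for leg in body.legs if leg.position == position)
        if pair > 0:
            out[f"{position}_leg_pair"] = pair / total * 100.0
    return out


def joint_torque_from_muscles(
    attachment: MuscleAttachment, f_agonist: float, f_antagonist: float
) -> float:
    """Net joint torque r_ago*F_ago - r_ant*F_ant (mN*mm); forces >= 0."""
    if f_agonist < 0 or f_antagonist < 0:
        raise ValueError("muscle forces must be non-negative")
    return (
        attachment.arm_agonist_mm * f_agonist
        - attachment.arm_antagonist_mm * f_antagonist
    )


def muscle_kinematics(
    attachment: MuscleAttachment, q: float, qdot: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Normalised (L_ce, V_ce) for the agonist and antagonist of a joint.

    The agonist produces positive joint torque, so it must shorten as the
    joint angle grows (it pulls the joint the way it torques); the
    antagonist mirrors it: L = 1 -/+ gain * (q - q_rest), V = -/+ gain *
    qdot.  With this pairing the concentric force-velocity drop opposes the
    motion each muscle drives — the muscle acts as a damper, not an
    anti-damper.
    """
    dq = q - attachment.q_rest
    ago = (1.0 - attachment.gain * dq, -attachment.gain * qdot)
    ant = (1.0 + attachment.gain * dq, attachment.gain * qdot)
    return ago, ant


# ---------------------------------------------------------------------------
# physics backend
# ---------------------------------------------------------------------------

@dataclass
class BodyState:
    """Trunk rigid-body state in world coordinates (mm, mm/s, rad)."""

    position: np.ndarray  # (3,)
    velocity: np.ndarray  # (3,)
    yaw: float = 0.0
    yaw_rate: float = 0.0

    def copy(self) -> "BodyState":
        return BodyState(
            self.position.copy(), self.velocity.copy(), self.yaw, self.yaw_rate
        )


class PhysicsBackend:
    """Contract for articulated rigid-body stepping.

    Implementations advance the body under applied stance-leg joint torques
    and kinematic swing targets, deterministically for identical inputs, and
    report per-foot ground reaction forces.  A backend must fail at
    construction time if unusable, never mid-run.
    """

    dt_s: float

    def reset(self, yaw: float = 0.0) -> BodyState:  # pragma: no cover - contract
        raise NotImplementedError

    def step(self, state: BodyState, stance: dict) -> tuple[BodyState, dict]:
        raise NotImplementedError  # pragma: no cover - contract


class ReducedBackend(PhysicsBackend):
    """Deterministic reduced rigid-body dynamics.

    The trunk is one rigid body.  Each stance leg is a massless transmission:
    static balance of the massless chain (``tau + J^T f = 0``) gives the
    ground reaction ``f = -solve(J(q)^T, tau)`` (mN, body frame) that the leg
    passes to the trunk, with the vertical component clamped non-negative
    (the ground cannot pull) and the magnitude capped to keep near-singular
    postures finite.  Trunk translation integrates the
    summed ground reactions, gravity (tilted by the slope angle) and viscous
    damping; height relaxes on a damped-strut law driven by the vertical
    support ratio; yaw follows a first-order turning law pivoting toward the
    side with the greater propulsive impulse.
    """

    def __init__(
        self,
        body: BodyModel,
        dt_s: float = 0.005,
        slope_deg: float = 0.0,
        gravity_mm_s2: float = GRAVITY_MM_S2,
        lin_damping_mn_per_mm_s: float = 1.2e-3,
        sink_rate_per_s: float = 8.0,
        turn_rate_gain_rad_s_per_mn: float = 10.0,
        yaw_time_constant_s: float = 0.5,
        yaw_anchor_rate_per_s: float = 20.0,
        force_cap_body_weights: float = 5.0,
        passive_support_fraction: float = 0.9,
    ) -> None:
        if dt_s <= 0:
            raise ValueError("dt_s must be positive")
        self.body = body
        self.dt_s = dt_s
        self.slope_rad = np.deg2rad(slope_deg)
        self.g = gravity_mm_s2
        self.lin_damping = lin_damping_mn_per_mm_s
        self.sink_rate = sink_rate_per_s
        self.turn_gain = turn_rate_gain_rad_s_per_mn
        self.yaw_tau = yaw_time_constant_s
        self.yaw_anchor_rate = yaw_anchor_rate_per_s
        # share of the standing load carried by passive joint stiffness and
        # the exoskeleton whenever at least one leg is grounded; active
        # muscle force modulates support around it
        self.passive_fraction = passive_support_fraction
        self.mass_mg = body.total_mass_mg
        self.weight_mn = self.mass_mg * self.g * 1e-6  # mg * mm/s^2 -> mN
        self.force_cap_mn = force_cap_body_weights * max(self.weight_mn, 1e-12)
        self.standing_height = body.standing_height_mm

    def reset(self, yaw: float = 0.0) -> BodyState:
        return BodyState(
            position=np.array([0.0, 0.0, self.standing_height]),
            velocity=np.zeros(3),
            yaw=yaw,
        )

    def _leg_force(self, leg_idx: int, q: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Ground reaction (mN, body frame) transmitted by one stance leg."""
        jac = leg_jacobian(self.body.legs[leg_idx], q)
        jt = jac.T
        tau = np.asarray(tau, dtype=float)
        ok, f0, f1, f2 = _solve3(
            jt[0, 0], jt[0, 1], jt[0, 2],
            jt[1, 0], jt[1, 1], jt[1, 2],
            jt[2, 0], jt[2, 1], jt[2, 2],
            tau[0], tau[1], tau[2],
        )
        if ok:
            f = np.array([-f0, -f1, -f2])
        else:  # singular transmission: least-squares fallback
            f = -np.linalg.lstsq(jt, tau, rcond=None)[0]
        if not np.isfinite(f).all():
            f = np.zeros(3)
        f[2] = max(f[2], 0.0)  # unilateral contact
        norm = np.linalg.norm(f)
        if norm > self.force_cap_mn:
            f *= self.force_cap_mn / norm
        return f

    def step(
        self, state: BodyState, stance: dict, anchor_yaw: float | None = None
    ) -> tuple[BodyState, dict]:
        """Advance one step.

        ``stance`` maps leg index -> (q, tau) for dynamically actuated legs.
        ``anchor_yaw`` is the heading at the current stance set's touchdown:
        pinned feet resist body rotation, so yaw is sprung toward it (a
        sustained drive asymmetry still turns, because every touchdown
        re-anchors at the yaw then reached).  Returns the new state and the
        world-frame ground reaction per stance leg (mN).
        """
        dt = self.dt_s
        cy, sy = np.cos(state.yaw), np.sin(state.yaw)
        rot = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
        total_world = np.zeros(3)
        turn_moment = 0.0
        grf: dict[int, np.ndarray] = {}
        for leg_idx, (q, tau) in stance.items():
            f_body = self._leg_force(leg_idx, np.asarray(q), np.asarray(tau))
            grf[leg_idx] = rot @ f_body
            total_world += grf[leg_idx]
            # propulsive component along the body axis, signed by side:
            # the body pivots toward the side pushing harder
            turn_moment += self.body.legs[leg_idx].side * f_body[0]

        new = state.copy()
        if self.g > 0:
            # horizontal dynamics: reactions + slope gravity, with the
            # viscous drag integrated implicitly so large damping rates
            # remain stable at the 5 ms step
            g_world = self.g * np.array([-np.sin(self.slope_rad), 0.0])
            acc = 1e6 * total_world[:2] / self.mass_mg + g_world
            damp_rate = 1e6 * self.lin_damping / self.mass_mg
            new.velocity[:2] = (state.velocity[:2] + acc * dt) / (1.0 + damp_rate * dt)
            new.position[:2] = state.position[:2] + new.velocity[:2] * dt
            # damped-strut height: sink on support deficit, recover on surplus
            w_eff = self.weight_mn * np.cos(self.slope_rad)
            passive = self.passive_fraction * w_eff if stance else 0.0
            support = (total_world[2] + passive) / w_eff
            rate = self.sink_rate * (min(support, 1.5) - 1.0)
            vz = rate * self.standing_height
            new_z = state.position[2] + vz * dt
            # struts cannot push above standing height; the ground stops sinking
            new.position[2] = min(max(new_z, 0.0), self.standing_height)
            new.velocity[2] = (new.position[2] - state.position[2]) / dt
        else:
            # zero gravity: pure ballistic reactions (unchanged when idle)
            acc = 1e6 * total_world / self.mass_mg
            new.velocity = state.velocity + acc * dt
            new.position = state.position + new.velocity * dt
        # first-order yaw response: the target rate combines the propulsive
        # side difference (the body pivots toward the side pushing harder)
        # with the stance anchor restoring term (pinned feet resist body
        # rotation); the time constant filters the alternating tripod
        # component so only a sustained asymmetry turns
        target_rate = self.turn_gain * turn_moment
        if anchor_yaw is not None and stance:
            target_rate -= self.yaw_anchor_rate * (state.yaw - anchor_yaw)
        new.yaw_rate = state.yaw_rate + dt * (target_rate - state.yaw_rate) / self.yaw_tau
        new.yaw = state.yaw + new.yaw_rate * dt
        return new, grf
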