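"""The 26-segment kinematic tree of the foot: segments, joints, forward kinematics.

The model is a rigid-body tree rooted at the tibia. Each of the 26 foot bones
(7 tarsals, 5 metatarsals, 14 phalanges) is one segment, connected to its
parent by a revolute (1 DoF), universal (2 DoF) or spherical (3 DoF) joint:
ankle and subtalar revolute, talonavicular and calcaneocuboid spherical,
the three cuneonavicular and all tarsometatarsal and metatarsophalangeal
joints universal, all interphalangeal joints revolute — 43 joint DoF in all.

Conventions
-----------
* Lab frame: X anterior, Y medial (right foot), Z up; meters and radians.
* At the neutral (all-zero) state every segment frame is axis-aligned with
  its parent; a segment's origin sits at its connecting joint center.
* Each joint rotates about 1–3 ordered unit axes given in the parent frame,
  composed first-axis-first (intrinsic). Positive angles follow the clinical
  convention: plantarflexion, inversion and adduction positive, encoded by a
  per-DoF sign in :class:`JointSpec`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, TemplateError
from .geometry import EllipsoidSurface, compose_axis_rotations, rodrigues

__all__ = [
    "Segment",
    "JointSpec",
    "KinematicTemplate",
    "JointState",
    "joint_transform",
    "forward_kinematics",
    "marker_positions",
    "default_template",
    "load_template",
    "save_template",
    "FOOT_SEGMENTS",
    "LANDMARK_NAMES",
]

JOINT_DOF = {"revolute": 1, "universal": 2, "spherical": 3}

# Ordered rotation axes of the root pose: R_root = Rz(rz) @ Ry(ry) @ Rx(rx).
ROOT_ROT_AXES = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])

#: The canonical 16 scan landmarks used by the scaling module.
LANDMARK_NAMES = (
    "post_calcaneus",
    "plantar_heel_central",
    "heel_medial",
    "heel_lateral",
    "achilles_between_malleoli",
    "malleolus_medial",
    "malleolus_lateral",
    "navicular_tuberosity",
    "navicular_dorsal",
    "mt5_base",
    "mt1_head_medial",
    "tmt2_dorsal",
    "mtp3_plantar",
    "hallux_tip",
    "toe2_tip",
    "toe5_tip",
)

_TARSALS = (
    "talus",
    "calcaneus",
    "navicular",
    "cuboid",
    "medial_cuneiform",
    "central_cuneiform",
    "lateral_cuneiform",
)
_METATARSALS = tuple(f"metatarsal_{i}" for i in range(1, 6))
_PHALANGES = (
    tuple(f"proximal_phalanx_{i}" for i in range(1, 6))
    + tuple(f"central_phalanx_{i}" for i in range(2, 6))
    + tuple(f"distal_phalanx_{i}" for i in range(1, 6))
)
#: The 26 foot bones of the canonical model (root tibia excluded).
FOOT_SEGMENTS = _TARSALS + _METATARSALS + _PHALANGES

_DISPLAY = {
    "tibia": "Tibia",
    "talus": "Talus",
    "calcaneus": "Calcaneus",
    "navicular": "Navicular",
    "cuboid": "Cuboid",
    "medial_cuneiform": "Medial Cuneiform",
    "central_cuneiform": "Central Cuneiform",
    "lateral_cuneiform": "Lateral Cuneiform",
}
for _i in range(1, 6):
    _DISPLAY[f"metatarsal_{_i}"] = f"Metatarsal {_i}"
    _DISPLAY[f"proximal_phalanx_{_i}"] = f"Proximal Phalange {_i}"
    _DISPLAY[f"distal_phalanx_{_i}"] = f"Distal Phalange {_i}"
for _i in range(2, 6):
    _DISPLAY[f"central_phalanx_{_i}"] = f"Central Phalange {_i}"


def display_name(segment: str) -> str:
    return _DISPLAY.get(segment, segment.replace("_", " ").title())


@dataclass
class Segment:
    """One rigid bone segment of the tree.

    ``local_joint_center`` is the position of this segment's connecting joint
    (= its frame origin at neutral) expressed in the parent frame; attachment
    points (``marker_points``, ``landmark_points``) are in this segment's frame.
    """

    name: str
    parent: str | None
    local_joint_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    marker_points: dict[str, np.ndarray] = field(default_factory=dict)
    landmark_points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.local_joint_center = np.asarray(
            self.local_joint_center, dtype=float
        ).reshape(3)
        self.marker_points = {
            k: np.asarray(v, dtype=float).reshape(3)
            for k, v in self.marker_points.items()
        }
        self.landmark_points = {
            k: np.asarray(v, dtype=float).reshape(3)
            for k, v in self.landmark_points.items()
        }


@dataclass
class JointSpec:
    """Parameterization of the joint connecting ``child_segment`` to its parent."""

    child_segment: str
    joint_type: str  # revolute | universal | spherical
    axes: np.ndarray  # (dof, 3) ordered unit axes in the parent frame
    angle_names: tuple[str, ...]  # clinical labels, e.g. ("plantarflexion",)
    sign_convention: tuple[int, ...] | None = None  # +1/-1 per DoF
    limits: np.ndarray | None = None  # (dof, 2) radians

    def __post_init__(self) -> None:
        if self.joint_type not in JOINT_DOF:
            raise TemplateError(f"unknown joint type {self.joint_type!r}")
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        n = JOINT_DOF[self.joint_type]
        if self.axes.shape != (n, 3):
            raise TemplateError(
                f"{self.joint_type} joint of {self.child_segment!r} needs "
                f"{n} axes, got shape {self.axes.shape}"
            )
        norms = np.linalg.norm(self.axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise TemplateError(
                f"joint axes of {self.child_segment!r} must be unit-norm"
            )
        if n == 2:
            cross = np.linalg.norm(np.cross(self.axes[0], self.axes[1]))
            if cross < 1e-9:
                raise TemplateError(
                    f"universal joint of {self.child_segment!r} has parallel axes"
                )
        self.angle_names = tuple(self.angle_names)
        if len(self.angle_names) != n:
            raise TemplateError(
                f"joint of {self.child_segment!r}: {len(self.angle_names)} "
                f"angle names for {n} DoF"
            )
        if self.sign_convention is None:
            self.sign_convention = (1,) * n
        self.sign_convention = tuple(int(s) for s in self.sign_convention)
        if len(self.sign_convention) != n or any(
            s not in (-1, 1) for s in self.sign_convention
        ):
            raise TemplateError(
                f"sign convention of {self.child_segment!r} must be +/-1 per DoF"
            )
        if self.limits is None:
            self.limits = np.tile([-np.pi / 2, np.pi / 2], (n, 1))
        self.limits = np.asarray(self.limits, dtype=float).reshape(n, 2)

    @property
    def dof(self) -> int:
        return JOINT_DOF[self.joint_type]


def joint_transform(
    spec: JointSpec, angles, joint_center=None
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform of the child frame in the parent frame.

    Rotation about the ordered joint axes (first axis applied first, signs
    from the spec's convention), translation to the joint center.
    Returns ``(R, t)`` with ``x_parent = R @ x_child + t``.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.shape != (spec.dof,):
        raise DimensionError(
            f"joint of {spec.child_segment!r} expects {spec.dof} angles, "
            f"got {angles.shape}"
        )
    if not np.all(np.isfinite(angles)):
        raise ValueError(f"non-finite joint angle for {spec.child_segment!r}")
    signed = angles * np.asarray(spec.sign_convention, dtype=float)
    R = compose_axis_rotations(spec.axes, signed)
    t = (
        np.zeros(3)
        if joint_center is None
        else np.asarray(joint_center, dtype=float).reshape(3)
    )
    return R, t


class KinematicTemplate:
    """A validated kinematic tree plus contact-surface and rhythm metadata.

    Generic trees (e.g. two-link toy chains in tests) are allowed; the
    canonical foot template additionally satisfies
    :meth:`validate_foot_inventory`.
    """

    def __init__(
        self,
        segments: list[Segment],
        joints: list[JointSpec],
        contact_surfaces: dict[str, EllipsoidSurface] | None = None,
        contact_pairs: list[tuple[str, str]] | None = None,
        rhythm_config: dict | None = None,
        name: str = "template",
    ) -> None:
        self.segments = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise TemplateError("duplicate segment names")
        self.joints = {j.child_segment: j for j in joints}
        if len(self.joints) != len(joints):
            raise TemplateError("more than one joint for a segment")
        self.contact_surfaces = dict(contact_surfaces or {})
        self.contact_pairs = [tuple(p) for p in (contact_pairs or [])]
        self.rhythm_config = rhythm_config
        self.name = name
        self._validate_tree()
        self._index()

    # -- structure ---------------------------------------------------------
    def _validate_tree(self) -> None:
        roots = [s for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise TemplateError(f"expected exactly one root segment, got {len(roots)}")
        self.root = roots[0].name
        for s in self.segments.values():
            if s.parent is not None and s.parent not in self.segments:
                raise TemplateError(f"{s.name!r} references unknown parent {s.parent!r}")
        # reachability from the root proves the parent map is a tree
        children: dict[str, list[str]] = {n: [] for n in self.segments}
        for s in self.segments.values():
            if s.parent is not None:
                children[s.parent].append(s.name)
        order: list[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(reversed(children[n]))
        if len(order) != len(self.segments):
            unreachable = set(self.segments) - set(order)
            raise TemplateError(f"cycle or orphan segments: {sorted(unreachable)}")
        self.children = children
        self.topo_order = order
        for s in self.segments.values():
            if s.parent is None:
                continue
            if s.name not in self.joints:
                raise TemplateError(f"non-root segment {s.name!r} has no joint")
        for j in self.joints.values():
            if j.child_segment not in self.segments:
                raise TemplateError(f"joint for unknown segment {j.child_segment!r}")
            if self.segments[j.child_segment].parent is None:
                raise TemplateError("root segment cannot have a joint")

    def _index(self) -> None:
        # DoF layout follows the tree traversal order; within a joint, axis order.
        self.dof_index: dict[tuple[str, str], int] = {}
        self.dof_list: list[tuple[str, str]] = []
        for name in self.topo_order:
            j = self.joints.get(name)
            if j is None:
                continue
            for angle_name in j.angle_names:
                self.dof_index[(name, angle_name)] = len(self.dof_list)
                self.dof_list.append((name, angle_name))
        # ancestor DoF chain per segment, for geometric Jacobians
        self.chain_dofs: dict[str, list[int]] = {self.root: []}
        for name in self.topo_order:
            if name == self.root:
                continue
            parent = self.segments[name].parent
            own = [self.dof_index[(name, a)] for a in self.joints[name].angle_names]
            self.chain_dofs[name] = self.chain_dofs[parent] + own
        # marker/landmark ownership (names must be globally unique)
        self.marker_owner: dict[str, str] = {}
        self.landmark_owner: dict[str, str] = {}
        for s in self.segments.values():
            for m in s.marker_points:
                if m in self.marker_owner:
                    raise TemplateError(f"marker {m!r} attached to two segments")
                self.marker_owner[m] = s.name
            for m in s.landmark_points:
                if m in self.landmark_owner:
                    raise TemplateError(f"landmark {m!r} attached to two segments")
                self.landmark_owner[m] = s.name

    @property
    def total_dof(self) -> int:
        return len(self.dof_list)

    @property
    def marker_names(self) -> list[str]:
        return list(self.marker_owner)

    def dof_labels(self) -> list[str]:
        """Human-readable per-DoF labels: '(parent) to (child) - (plane)'."""
        out = []
        for child, angle in self.dof_list:
            parent = self.segments[child].parent
            out.append(
                f"{display_name(parent)} to {display_name(child)} - "
                f"{angle.capitalize()}"
            )
        return out

    def validate_foot_inventory(self) -> None:
        """Check the canonical 26-bone composition and the 43-DoF joint inventory."""
        non_root = set(self.segments) - {self.root}
        if non_root != set(FOOT_SEGMENTS):
            raise TemplateError("segment inventory does not match the 26 foot bones")
        expected_types = {
            "talus": "revolute",
            "calcaneus": "revolute",
            "navicular": "spherical",
            "cuboid": "spherical",
        }
        for c in ("medial_cuneiform", "central_cuneiform", "lateral_cuneiform"):
            expected_types[c] = "universal"
        for i in range(1, 6):
            expected_types[f"metatarsal_{i}"] = "universal"
            expected_types[f"proximal_phalanx_{i}"] = "universal"
            expected_types[f"distal_phalanx_{i}"] = "revolute"
        for i in range(2, 6):
            expected_types[f"central_phalanx_{i}"] = "revolute"
        for seg, jt in expected_types.items():
            if self.joints[seg].joint_type != jt:
                raise TemplateError(
                    f"{seg}: expected {jt} joint, got {self.joints[seg].joint_type}"
                )
        if self.total_dof != 43:
            raise TemplateError(f"expected 43 joint DoF, got {self.total_dof}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "name": self.name,
            "segments": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "local_joint_center": s.local_joint_center.tolist(),
                    "markers": {k: v.tolist() for k, v in s.marker_points.items()},
                    "landmarks": {k: v.tolist() for k, v in s.landmark_points.items()},
                }
                for s in (self.segments[n] for n in self.topo_order)
            ],
            "joints": [
                {
                    "child_segment": j.child_segment,
                    "joint_type": j.joint_type,
                    "axes": j.axes.tolist(),
                    "angle_names": list(j.angle_names),
                    "sign_convention": list(j.sign_convention),
                    "limits": j.limits.tolist(),
                }
                for j in (
                    self.joints[n] for n in self.topo_order if n in self.joints
                )
            ],
            "contact": {
                "surfaces": {k: e.to_dict() for k, e in self.contact_surfaces.items()},
                "pairs": [list(p) for p in self.contact_pairs],
            },
            "rhythms": self.rhythm_config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KinematicTemplate":
        if d.get("schema_version") != 1:
            raise TemplateError(
                f"unsupported template schema version {d.get('schema_version')!r}"
            )
        segments = [
            Segment(
                name=s["name"],
                parent=s["parent"],
                local_joint_center=s["local_joint_center"],
                marker_points=s.get("markers", {}),
                landmark_points=s.get("landmarks", {}),
            )
            for s in d["segments"]
        ]
        joints = [
            JointSpec(
                child_segment=j["child_segment"],
                joint_type=j["joint_type"],
                axes=np.array(j["axes"], dtype=float),
                angle_names=tuple(j["angle_names"]),
                sign_convention=tuple(j.get("sign_convention", ())) or None,
                limits=np.array(j["limits"], dtype=float) if "limits" in j else None,
            )
            for j in d["joints"]
        ]
        contact = d.get("contact") or {}
        return cls(
            segments,
            joints,
            contact_surfaces={
                k: EllipsoidSurface.from_dict(v)
                for k, v in (contact.get("surfaces") or {}).items()
            },
            contact_pairs=[tuple(p) for p in contact.get("pairs", [])],
            rhythm_config=d.get("rhythms"),
            name=d.get("name", "template"),
        )


def save_template(template: KinematicTemplate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(template.to_dict(), indent=1))


def load_template(path: str | Path) -> KinematicTemplate:
    return KinematicTemplate.from_dict(json.loads(Path(path).read_text()))


@dataclass
class JointState:
    """Generalized coordinates at one time sample.

    ``root_pose``: tibia pose in the lab frame, ``[tx, ty, tz, rx, ry, rz]``
    (m, rad) with rotation ``Rz(rz) @ Ry(ry) @ Rx(rx)``. ``q``: joint angles
    (rad) in the template's DoF order.
    """

    root_pose: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.root_pose = np.asarray(self.root_pose, dtype=float).reshape(6)
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if not (np.all(np.isfinite(self.root_pose)) and np.all(np.isfinite(self.q))):
            raise ValueError("joint state must be finite")

    @classmethod
    def zeros(cls, template: KinematicTemplate) -> "JointState":
        return cls(np.zeros(6), np.zeros(template.total_dof))

    def root_rotation(self) -> np.ndarray:
        rx, ry, rz = self.root_pose[3:]
        return compose_axis_rotations(ROOT_ROT_AXES, [rz, ry, rx])


class FkResult:
    """Poses plus per-DoF lab-frame axis data (feeds the IK Jacobian)."""

    __slots__ = ("poses", "dof_axes", "dof_centers", "root_axes", "root_origin")

    def __init__(self, poses, dof_axes, dof_centers, root_axes, root_origin):
        self.poses = poses  # segment -> (R, t)
        self.dof_axes = dof_axes  # (n_dof, 3) signed lab-frame rotation axes
        self.dof_centers = dof_centers  # (n_dof, 3) lab-frame joint centers
        self.root_axes = root_axes  # (3, 3) lab axes for (rz, ry, rx), in order
        self.root_origin = root_origin  # (3,)


def fk_full(template: KinematicTemplate, state: JointState) -> FkResult:
    """Forward kinematics with the per-DoF frames needed for Jacobians."""
    if state.q.shape != (template.total_dof,):
        raise DimensionError(
            f"state has {state.q.shape[0]} joint angles, template has "
            f"{template.total_dof} DoF"
        )
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n = template.total_dof
    dof_axes = np.zeros((n, 3))
    dof_centers = np.zeros((n, 3))

    t0 = state.root_pose[:3]
    rx, ry, rz = state.root_pose[3:]
    # root rotation = Rz Ry Rx; lab-frame axis of each successive rotation
    root_axes = np.zeros((3, 3))
    R = np.eye(3)
    for i, (ax, th) in enumerate(zip(ROOT_ROT_AXES, (rz, ry, rx))):
        root_axes[i] = R @ ax
        R = R @ rodrigues(ax, th)
    poses[template.root] = (R, t0.copy())

    for name in template.topo_order:
        if name == template.root:
            continue
        seg = template.segments[name]
        spec = template.joints[name]
        Rp, tp = poses[seg.parent]
        center = Rp @ seg.local_joint_center + tp
        Rj = np.eye(3)
        for k, angle_name in enumerate(spec.angle_names):
            idx = template.dof_index[(name, angle_name)]
            axis_parent = Rj @ spec.axes[k]
            dof_axes[idx] = spec.sign_convention[k] * (Rp @ axis_parent)
            dof_centers[idx] = center
            Rj = Rj @ rodrigues(
                spec.axes[k], spec.sign_convention[k] * state.q[idx]
            )
        poses[name] = (Rp @ Rj, center)
    return FkResult(poses, dof_axes, dof_centers, root_axes, t0.copy())


def point_jacobian(
    template: KinematicTemplate,
    fk: FkResult,
    segment: str,
    point_lab: np.ndarray,
) -> np.ndarray:
    """Geometric Jacobian (3 x (6 + n_dof)) of a lab point fixed to ``segment``.

    Columns follow the generalized-coordinate layout ``[tx, ty, tz, rx, ry,
    rz, q_0 .. q_{n-1}]``; each rotational column is ``axis x (p - center)``.
    """
    p = np.asarray(point_lab, dtype=float).reshape(3)
    J = np.zeros((3, 6 + template.total_dof))
    J[:, :3] = np.eye(3)
    r = p - fk.root_origin
    # root rotation is Rz(rz) Ry(ry) Rx(rx); fk.root_axes rows are (rz, ry, rx)
    J[:, 5] = np.cross(fk.root_axes[0], r)
    J[:, 4] = np.cross(fk.root_axes[1], r)
    J[:, 3] = np.cross(fk.root_axes[2], r)
    for d in template.chain_dofs[segment]:
        J[:, 6 + d] = np.cross(fk.dof_axes[d], p - fk.dof_centers[d])
    return J


def forward_kinematics(
    template: KinematicTemplate, state: JointState
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Lab-frame pose ``(R, t)`` of every segment (t = segment origin)."""
    return fk_full(template, state).poses


def marker_positions(
    template: KinematicTemplate,
    state: JointState,
    names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Lab-frame positions of the template's marker attachment points."""
    if not template.marker_owner:
        raise TemplateError("template defines no marker points")
    poses = forward_kinematics(template, state)
    if names is None:
        names = template.marker_names
    out = {}
    for m in names:
        if m not in template.marker_owner:
            raise KeyError(f"unknown marker {m!r}")
        seg = template.marker_owner[m]
        R, t = poses[seg]
        out[m] = R @ template.segments[seg].marker_points[m] + t
    return out


def landmark_positions(
    template: KinematicTemplate, state: JointState | None = None
) -> dict[str, np.ndarray]:
    """Lab-frame positions of the template's scan landmarks (neutral by default)."""
    if state is None:
        state = JointState.zeros(template)
    poses = forward_kinematics(template, state)
    out = {}
    for m, seg in template.landmark_owner.items():
        R, t = poses[seg]
        out[m] = R @ template.segments[seg].landmark_points[m] + t
    return out


# ---------------------------------------------------------------------------
# Canonical synthetic template
# ---------------------------------------------------------------------------

# Lab-frame positions at neutral of every joint center (m). Nominal adult
# right foot, length ~0.28 m heel to hallux tip, ankle joint at z = 0.08.
_JC = {
    "tibia": (0.0, 0.0, 0.40),  # root origin, mid-shank
    "talus": (0.0, 0.0, 0.080),  # ankle
    "calcaneus": (0.005, 0.0, 0.050),  # subtalar
    "navicular": (0.045, 0.010, 0.055),  # talonavicular
    "cuboid": (0.040, -0.020, 0.045),  # calcaneocuboid
    "medial_cuneiform": (0.075, 0.015, 0.055),
    "central_cuneiform": (0.075, 0.000, 0.052),
    "lateral_cuneiform": (0.075, -0.012, 0.050),
    "metatarsal_1": (0.105, 0.020, 0.050),
    "metatarsal_2": (0.105, 0.002, 0.050),
    "metatarsal_3": (0.105, -0.013, 0.047),
    "metatarsal_4": (0.095, -0.028, 0.042),
    "metatarsal_5": (0.090, -0.040, 0.038),
    "proximal_phalanx_1": (0.165, 0.028, 0.030),
    "proximal_phalanx_2": (0.172, 0.005, 0.030),
    "proximal_phalanx_3": (0.168, -0.012, 0.028),
    "proximal_phalanx_4": (0.160, -0.028, 0.026),
    "proximal_phalanx_5": (0.150, -0.042, 0.024),
    "distal_phalanx_1": (0.195, 0.030, 0.025),
    "central_phalanx_2": (0.197, 0.005, 0.024),
    "central_phalanx_3": (0.192, -0.013, 0.023),
    "central_phalanx_4": (0.183, -0.029, 0.022),
    "central_phalanx_5": (0.172, -0.043, 0.021),
    "distal_phalanx_2": (0.212, 0.005, 0.022),
    "distal_phalanx_3": (0.206, -0.013, 0.021),
    "distal_phalanx_4": (0.196, -0.030, 0.020),
    "distal_phalanx_5": (0.184, -0.044, 0.019),
}

_PARENT = {
    "talus": "tibia",
    "calcaneus": "talus",
    "navicular": "talus",
    "cuboid": "calcaneus",
    "medial_cuneiform": "navicular",
    "central_cuneiform": "navicular",
    "lateral_cuneiform": "navicular",
    "metatarsal_1": "medial_cuneiform",
    "metatarsal_2": "central_cuneiform",
    "metatarsal_3": "lateral_cuneiform",
    "metatarsal_4": "cuboid",
    "metatarsal_5": "cuboid",
    **{f"proximal_phalanx_{i}": f"metatarsal_{i}" for i in range(1, 6)},
    "distal_phalanx_1": "proximal_phalanx_1",
    **{f"central_phalanx_{i}": f"proximal_phalanx_{i}" for i in range(2, 6)},
    **{f"distal_phalanx_{i}": f"central_phalanx_{i}" for i in range(2, 6)},
}

# 43-marker protocol: lab-frame positions at neutral, grouped by owning segment.
_MARKERS = {
    "tibia": {
        "TIB_UP_ANT": (0.020, 0.000, 0.300),
        "TIB_UP_LAT": (0.000, -0.050, 0.300),
        "TIB_LO_ANT": (0.020, 0.000, 0.150),
        "TIB_LO_MED": (0.000, 0.045, 0.150),
        "MAL_MED": (0.005, 0.035, 0.090),
        "MAL_LAT": (0.005, -0.035, 0.085),
    },
    "calcaneus": {
        "HEEL_POST": (-0.058, 0.000, 0.035),
        "HEEL_MED": (-0.045, 0.025, 0.030),
        "HEEL_LAT": (-0.045, -0.028, 0.030),
    },
    "talus": {"TAL_DORS": (0.030, 0.005, 0.070)},
    "navicular": {
        "NAV_TUB": (0.055, 0.028, 0.045),
        "NAV_DORS": (0.058, 0.005, 0.068),
    },
    "cuboid": {
        "CUB_LAT": (0.058, -0.038, 0.040),
        "CUB_DORS": (0.062, -0.020, 0.058),
    },
    "medial_cuneiform": {"CUN_MED_DORS": (0.090, 0.018, 0.066)},
    "central_cuneiform": {"CUN_CEN_DORS": (0.090, 0.001, 0.066)},
    "lateral_cuneiform": {"CUN_LAT_DORS": (0.088, -0.014, 0.062)},
    "metatarsal_1": {
        "MT1_BASE": (0.112, 0.022, 0.060),
        "MT1_HEAD": (0.160, 0.028, 0.042),
        "MT1_MED": (0.135, 0.035, 0.040),
    },
    "metatarsal_2": {
        "MT2_BASE": (0.112, 0.003, 0.060),
        "MT2_HEAD": (0.167, 0.005, 0.040),
    },
    "metatarsal_3": {
        "MT3_BASE": (0.112, -0.013, 0.057),
        "MT3_HEAD": (0.163, -0.012, 0.038),
    },
    "metatarsal_4": {
        "MT4_BASE": (0.102, -0.028, 0.052),
        "MT4_HEAD": (0.155, -0.028, 0.036),
    },
    "metatarsal_5": {
        "MT5_BASE": (0.097, -0.042, 0.048),
        "MT5_HEAD": (0.145, -0.042, 0.034),
        "MT5_LAT": (0.120, -0.050, 0.030),
    },
    "proximal_phalanx_1": {"PP1": (0.182, 0.029, 0.030)},
    "proximal_phalanx_2": {"PP2": (0.186, 0.005, 0.029)},
    "proximal_phalanx_3": {"PP3": (0.181, -0.012, 0.027)},
    "proximal_phalanx_4": {"PP4": (0.173, -0.028, 0.025)},
    "proximal_phalanx_5": {"PP5": (0.162, -0.042, 0.024)},
    "central_phalanx_2": {"CP2": (0.206, 0.005, 0.025)},
    "central_phalanx_3": {"CP3": (0.200, -0.013, 0.024)},
    "central_phalanx_4": {"CP4": (0.190, -0.029, 0.023)},
    "central_phalanx_5": {"CP5": (0.179, -0.043, 0.021)},
    "distal_phalanx_1": {"TOE1_TIP": (0.215, 0.030, 0.018)},
    "distal_phalanx_2": {"TOE2_TIP": (0.224, 0.005, 0.016)},
    "distal_phalanx_3": {"TOE3_TIP": (0.217, -0.013, 0.016)},
    "distal_phalanx_4": {"TOE4_TIP": (0.207, -0.030, 0.015)},
    "distal_phalanx_5": {"TOE5_TIP": (0.194, -0.044, 0.015)},
}

# The 16 scan landmarks: (owning segment, lab position at neutral).
_LANDMARKS = {
    "post_calcaneus": ("calcaneus", (-0.060, 0.000, 0.045)),
    "plantar_heel_central": ("calcaneus", (-0.040, 0.000, 0.002)),
    "heel_medial": ("calcaneus", (-0.040, 0.030, 0.020)),
    "heel_lateral": ("calcaneus", (-0.040, -0.032, 0.020)),
    "achilles_between_malleoli": ("tibia", (-0.045, 0.000, 0.085)),
    "malleolus_medial": ("tibia", (0.005, 0.040, 0.090)),
    "malleolus_lateral": ("tibia", (0.005, -0.040, 0.082)),
    "navicular_tuberosity": ("navicular", (0.055, 0.032, 0.042)),
    "navicular_dorsal": ("navicular", (0.058, 0.005, 0.070)),
    "mt5_base": ("metatarsal_5", (0.095, -0.048, 0.040)),
    "mt1_head_medial": ("metatarsal_1", (0.162, 0.040, 0.035)),
    "tmt2_dorsal": ("metatarsal_2", (0.108, 0.002, 0.062)),
    "mtp3_plantar": ("metatarsal_3", (0.168, -0.012, 0.005)),
    "hallux_tip": ("distal_phalanx_1", (0.218, 0.030, 0.012)),
    "toe2_tip": ("distal_phalanx_2", (0.227, 0.005, 0.012)),
    "toe5_tip": ("distal_phalanx_5", (0.197, -0.044, 0.012)),
}

# Clinical rotation axes in the parent frame (before per-DoF sign):
# plantarflexion about +Y, inversion about -X, adduction about +Z.
_AX_PF = (0.0, 1.0, 0.0)
_AX_INV = (1.0, 0.0, 0.0)
_AX_ADD = (0.0, 0.0, 1.0)


def _subtalar_axis() -> tuple[float, float, float]:
    # Classical inclined subtalar axis: 42 deg up from horizontal in the
    # sagittal plane, 23 deg medial in the transverse plane.
    s, t = np.deg2rad(42.0), np.deg2rad(23.0)
    v = np.array([np.cos(s) * np.cos(t), np.cos(s) * np.sin(t), np.sin(s)])
    return tuple(v / np.linalg.norm(v))


def _default_contact() -> tuple[dict[str, EllipsoidSurface], list[tuple[str, str]]]:
    # Gliding surfaces for the articulations without idealized joints:
    # cuboid-navicular, cuneocuboid and the two intercuneiform joints.
    # Hand-placed with ~1-4 mm clearance at the neutral pose; local = lab
    # position minus the owning segment's neutral origin.
    lab_centers = {
        "navicular": (0.058, 0.003, 0.053),
        "cuboid": (0.060, -0.025, 0.044),
        "medial_cuneiform": (0.090, 0.018, 0.052),
        "central_cuneiform": (0.090, 0.001, 0.050),
        "lateral_cuneiform": (0.088, -0.014, 0.048),
    }
    semi = {
        "navicular": (0.010, 0.008, 0.008),
        "cuboid": (0.014, 0.009, 0.009),
        "medial_cuneiform": (0.012, 0.0065, 0.008),
        "central_cuneiform": (0.012, 0.0065, 0.008),
        "lateral_cuneiform": (0.012, 0.0065, 0.008),
    }
    surfaces = {}
    for seg, c in lab_centers.items():
        local = np.array(c) - np.array(_JC[seg])
        surfaces[seg] = EllipsoidSurface(center=local, semi_axes=semi[seg])
    pairs = [
        ("navicular", "cuboid"),
        ("lateral_cuneiform", "cuboid"),
        ("medial_cuneiform", "central_cuneiform"),
        ("central_cuneiform", "lateral_cuneiform"),
    ]
    return surfaces, pairs


def default_template() -> KinematicTemplate:
    """The nominal adult foot template (synthetic geometry, editable via JSON).

    Joint centers, axes, markers and landmarks are plausible hand-set values
    for a right foot of ~28 cm; they parameterize the model and can be
    replaced wholesale through the JSON template file.
    """
    segments = []
    for name, jc in _JC.items():
        parent = _PARENT.get(name)
        origin = np.array(jc)
        local_jc = origin - np.array(_JC[parent]) if parent else np.zeros(3)
        markers = {
            m: np.array(p) - origin for m, p in _MARKERS.get(name, {}).items()
        }
        landmarks = {
            lm: np.array(p) - origin
            for lm, (seg, p) in _LANDMARKS.items()
            if seg == name
        }
        segments.append(
            Segment(
                name=name,
                parent=parent,
                local_joint_center=local_jc,
                marker_points=markers,
                landmark_points=landmarks,
            )
        )

    def rev(child, axis, angle, sign=1, lim=(-1.2, 1.2)):
        return JointSpec(child, "revolute", [axis], (angle,), (sign,), [lim])

    def uni(child, lim=(-1.2, 1.2)):
        return JointSpec(
            child,
            "universal",
            [_AX_PF, _AX_ADD],
            ("plantarflexion", "adduction"),
            (1, 1),
            [lim, lim],
        )

    def sph(child, lim=(-1.2, 1.2)):
        return JointSpec(
            child,
            "spherical",
            [_AX_PF, _AX_INV, _AX_ADD],
            ("plantarflexion", "inversion", "adduction"),
            (1, 1, 1),
            [lim, lim, lim],
        )

    joints = [
        rev("talus", _AX_PF, "plantarflexion"),  # ankle, mediolateral axis
        rev("calcaneus", _subtalar_axis(), "inversion"),  # subtalar
        sph("navicular"),  # talonavicular
        sph("cuboid"),  # calcaneocuboid
        uni("medial_cuneiform"),
        uni("central_cuneiform"),
        uni("lateral_cuneiform"),
        *[uni(f"metatarsal_{i}") for i in range(1, 6)],
        *[uni(f"proximal_phalanx_{i}") for i in range(1, 6)],
        rev("distal_phalanx_1", _AX_PF, "plantarflexion"),
        *[rev(f"central_phalanx_{i}", _AX_PF, "plantarflexion") for i in range(2, 6)],
        *[rev(f"distal_phalanx_{i}", _AX_PF, "plantarflexion") for i in range(2, 6)],
    ]
    surfaces, pairs = _default_contact()
    template = KinematicTemplate(
        segments,
        joints,
        contact_surfaces=surfaces,
        contact_pairs=pairs,
        name="gm26-default",
    )
    template.validate_foot_inventory()
    return template
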