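"""Rigid-body skeleton of the skier: segment/joint tree, generalized-coordinate
bookkeeping, forward kinematics, whole-body mass properties and the passive
ski-boot ankle moment.

The skeleton is a tree of segments connected by joints of kind ``free6``
(pelvis-to-ground), ``planar3`` (in-plane translation + pitch, used by the
reduced model), ``ball3`` (Z-X-Y Euler sequence, i.e. tilt/list/rotation),
``revolute1`` or ``locked``.  Locked joints contribute no coordinates; welded
subtrees (arms, head, skis) can be lumped into their carrier via
:meth:`MultibodyModel.lumped_mass_properties`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import load_model_config

_G = 9.81

_KIND_NDOF = {"free6": 6, "planar3": 3, "ball3": 3, "revolute1": 1, "locked": 0}
_DEFAULT_SUFFIXES = {
    "free6": ["x", "y", "z", "tilt", "list", "rot"],
    "planar3": ["x", "z", "pitch"],
    "ball3": ["tilt", "list", "rot"],
    "revolute1": ["angle"],
    "locked": [],
}


class ModelStructureError(ValueError):
    """Cyclic/disconnected segment graph or ill-formed joint layout."""


@dataclass
class SegmentSpec:
    name: str
    mass: float
    inertia: np.ndarray            # 3x3 about segment COM, segment frame
    com_offset: np.ndarray         # from proximal joint frame origin, m
    parent_joint: str = ""

    def __post_init__(self):
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        self.com_offset = np.asarray(self.com_offset, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ValueError(f"segment {self.name!r}: mass must be positive")
        if not np.allclose(self.inertia, self.inertia.T):
            raise ValueError(f"segment {self.name!r}: inertia must be symmetric")
        if np.min(np.linalg.eigvalsh(self.inertia)) < -1e-12:
            raise ValueError(f"segment {self.name!r}: inertia must be PSD")


@dataclass
class JointSpec:
    name: str
    kind: str
    parent: str
    child: str
    location_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray | None = None
    fixed_rotation: np.ndarray | None = None     # rad ZXY, locked joints only
    coord_names: list[str] | None = None

    def __post_init__(self):
        if self.kind not in _KIND_NDOF:
            raise ValueError(f"joint {self.name!r}: unknown kind {self.kind!r}")
        self.location_in_parent = np.asarray(self.location_in_parent, dtype=float).reshape(3)
        if self.kind == "revolute1":
            self.axis = np.asarray(self.axis, dtype=float).reshape(3)
            n = np.linalg.norm(self.axis)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError(f"joint {self.name!r}: revolute axis must be unit norm")

    @property
    def ndof(self) -> int:
        return _KIND_NDOF[self.kind]

    def coordinate_names(self) -> list[str]:
        suffixes = self.coord_names or _DEFAULT_SUFFIXES[self.kind]
        if len(suffixes) != self.ndof:
            raise ValueError(f"joint {self.name!r}: expected {self.ndof} coordinate names")
        return [f"{self.name}_{s}" for s in suffixes]


@dataclass
class BootParams:
    """Nonlinear passive ankle moment of the ski boot.

    Elastic part: odd deadband-filtered linear+cubic curve about the neutral
    angle; linear damping on the ankle rate.  The deflection passes through
    ``delta - d*tanh(delta/d)`` so the boot is soft within ~``deadband`` and
    stiffens smoothly outside it.
    """

    neutral_angle: float = 0.0       # rad
    stiffness_linear: float = 60.0   # N*m/rad
    stiffness_cubic: float = 900.0   # N*m/rad^3
    deadband: float = 0.035          # rad
    damping: float = 1.5             # N*m*s/rad

    @classmethod
    def from_config(cls, cfg: dict) -> "BootParams":
        return cls(
            neutral_angle=np.deg2rad(cfg.get("neutral_angle_deg", 0.0)),
            stiffness_linear=cfg.get("stiffness_linear", 60.0),
            stiffness_cubic=cfg.get("stiffness_cubic", 900.0),
            deadband=np.deg2rad(cfg.get("deadband_deg", 2.0)),
            damping=cfg.get("damping", 1.5),
        )


def boot_moment(ankle_angle, ankle_rate, params: BootParams):
    """Passive boot moment (N*m) opposing deflection from the neutral angle."""
    delta = ankle_angle - params.neutral_angle
    d = max(params.deadband, 1e-9)
    eff = delta - d * np.tanh(delta / d)
    elastic = params.stiffness_linear * eff + params.stiffness_cubic * eff**3
    return -elastic - params.damping * ankle_rate


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rot_zxy(tilt, lst, rot):
    """Extrinsic Z-X-Y rotation (tilt about z, list about x, rotation about y)."""
    return _rot_y(rot) @ _rot_x(lst) @ _rot_z(tilt)


def _axis_angle(axis, a):
    axis = np.asarray(axis, dtype=float)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _joint_transform(joint: JointSpec, qj: np.ndarray):
    """(R, p) of the child frame relative to the joint location in the parent."""
    if joint.kind == "locked":
        R = rot_zxy(*joint.fixed_rotation) if joint.fixed_rotation is not None else np.eye(3)
        return R, np.zeros(3)
    if joint.kind == "revolute1":
        return _axis_angle(joint.axis, qj[0]), np.zeros(3)
    if joint.kind == "ball3":
        return rot_zxy(qj[0], qj[1], qj[2]), np.zeros(3)
    if joint.kind == "planar3":
        return _rot_y(qj[2]), np.array([qj[0], 0.0, qj[1]])
    if joint.kind == "free6":
        return rot_zxy(qj[3], qj[4], qj[5]), qj[:3]
    raise AssertionError(joint.kind)


class MultibodyModel:
    """Segment/joint tree with coordinate layout and forward kinematics."""

    def __init__(self, segments: list[SegmentSpec], joints: list[JointSpec],
                 boot: BootParams | None = None, config: dict | None = None):
        self.boot = boot or BootParams()
        self.config = config or {}
        self.segments = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise ModelStructureError("duplicate segment names")
        self.joints = {}
        child_of: dict[str, str] = {}
        for j in joints:
            if j.child in child_of:
                raise ModelStructureError(f"segment {j.child!r} has two parent joints")
            if j.child not in self.segments:
                raise ModelStructureError(f"joint {j.name!r}: unknown child {j.child!r}")
            if j.parent != "ground" and j.parent not in self.segments:
                raise ModelStructureError(f"joint {j.name!r}: unknown parent {j.parent!r}")
            child_of[j.child] = j.name
            self.joints[j.name] = j
            self.segments[j.child].parent_joint = j.name
        # topological order from ground; detects cycles/disconnection
        self._order: list[JointSpec] = []
        placed = {"ground"}
        pending = list(joints)
        while pending:
            progress = [j for j in pending if j.parent in placed]
            if not progress:
                raise ModelStructureError("cyclic or disconnected segment graph")
            for j in progress:
                self._order.append(j)
                placed.add(j.child)
                pending.remove(j)
        roots = [j for j in self._order if j.parent == "ground"]
        if len(roots) != 1:
            raise ModelStructureError("model must have exactly one joint rooted at ground")
        # coordinate layout
        self.coordinate_names: list[str] = []
        self._coord_slice: dict[str, slice] = {}
        for j in self._order:
            start = len(self.coordinate_names)
            self.coordinate_names.extend(j.coordinate_names())
            self._coord_slice[j.name] = slice(start, len(self.coordinate_names))

    @property
    def ndof(self) -> int:
        return len(self.coordinate_names)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    def coord_index(self, name: str) -> int:
        return self.coordinate_names.index(name)

    def forward_kinematics(self, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World pose (position, 3x3 orientation) of every segment frame."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self.ndof,):
            raise ValueError(f"expected q of length {self.ndof}, got {q.shape}")
        poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for j in self._order:
            if j.parent == "ground":
                p_par, R_par = np.zeros(3), np.eye(3)
            else:
                p_par, R_par = poses[j.parent]
            Rj, pj = _joint_transform(j, q[self._coord_slice[j.name]])
            p = p_par + R_par @ j.location_in_parent + R_par @ pj
            poses[j.child] = (p, R_par @ Rj)
        return poses

    def whole_body_com(self, q: np.ndarray) -> np.ndarray:
        poses = self.forward_kinematics(q)
        acc = np.zeros(3)
        for name, seg in self.segments.items():
            p, R = poses[name]
            acc += seg.mass * (p + R @ seg.com_offset)
        return acc / self.total_mass

    def subtree_segments(self, root: str, locked_only: bool = False) -> list[str]:
        out, frontier = [root], [root]
        while frontier:
            nxt = []
            for j in self._order:
                if j.parent in frontier and not (locked_only and j.kind != "locked"):
                    out.append(j.child)
                    nxt.append(j.child)
            frontier = nxt
        return out

    def lumped_mass_properties(self, root: str, q: np.ndarray | None = None):
        """(mass, com, inertia about com) of the welded assembly formed by
        ``root`` and every descendant reachable through locked joints only,
        expressed in the root segment's frame.  Traversal stops at moving
        joints, so e.g. lumping the torso folds in head and arms but not legs.
        """
        names = self.subtree_segments(root, locked_only=True)
        q0 = np.zeros(self.ndof) if q is None else q
        poses = self.forward_kinematics(q0)
        p_root, R_root = poses[root]
        m_tot, first = 0.0, np.zeros(3)
        parts = []
        for n in names:
            seg = self.segments[n]
            p, R = poses[n]
            com_w = p + R @ seg.com_offset
            com_root = R_root.T @ (com_w - p_root)
            R_rel = R_root.T @ R
            parts.append((seg, com_root, R_rel))
            m_tot += seg.mass
            first += seg.mass * com_root
        com = first / m_tot
        inertia = np.zeros((3, 3))
        for seg, c, R_rel in parts:
            I_rot = R_rel @ seg.inertia @ R_rel.T
            d = c - com
            inertia += I_rot + seg.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
        return m_tot, com, inertia


def build_skier_model(config: dict | str) -> MultibodyModel:
    """Build the skier skeleton from a model configuration (dict or preset name).

    The configured tree must be rooted at a single ground joint; DOF count is
    the sum of unlocked joint coordinates (19 for the nominal 3D preset).
    """
    cfg = load_model_config(config) if isinstance(config, str) else config
    segments = [
        SegmentSpec(
            name=s["name"], mass=s["mass"],
            inertia=np.diag(s["inertia_diag"]) if "inertia_diag" in s else s["inertia"],
            com_offset=s["com_offset"],
        )
        for s in cfg["segments"]
    ]
    joints = []
    for j in cfg["joints"]:
        joints.append(JointSpec(
            name=j["name"], kind=j["kind"], parent=j["parent"], child=j["child"],
            location_in_parent=j.get("location_in_parent", np.zeros(3)),
            axis=j.get("axis"),
            fixed_rotation=np.deg2rad(j["fixed_rotation_deg"]) if "fixed_rotation_deg" in j else None,
            coord_names=j.get("coord_names"),
        ))
    boot = BootParams.from_config(cfg.get("boot", {}))
    return MultibodyModel(segments, joints, boot=boot, config=cfg)
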