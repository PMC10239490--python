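"""Planar (sagittal-plane) articulated rigid-body engine.

A :class:`PlanarModel` is a tree of bodies in the x-z plane: a free root
(coordinates x, z, pitch) and revolute descendants.  The engine provides
batched, complex-step-differentiable kinematics (positions, velocities,
accelerations of body frames, COMs and arbitrary body-fixed points),
generalized-force mapping of applied point loads, and inverse dynamics by
Jacobian projection:

    Q_needed[j] = sum_b (m_b a_cb - m_b g - F_b) . dp_cb/dq_j
                  + (I_b alpha_b - N_b) . dphi_b/dq_j

The implicit multibody residual is then ``Q_needed - Q_actuation = 0``.  All
arrays broadcast over a leading batch axis, and every operation is analytic so
Jacobians can be taken by complex step.

Models are built either from a 3D model config (projecting welded assemblies
onto the plane, transverse-axis inertia) or directly, e.g. for the segmented
ski chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81


@dataclass
class PlanarBody:
    name: str
    mass: float
    inertia: float                 # about COM, transverse axis, kg m^2
    com_offset: np.ndarray         # (2,) in body frame, from body origin (= joint pivot)
    parent: str | None = None      # None for the free root
    pivot_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(2))
    points: dict[str, np.ndarray] = field(default_factory=dict)   # named body-fixed points

    def __post_init__(self):
        self.com_offset = np.asarray(self.com_offset, dtype=float).reshape(2)
        self.pivot_in_parent = np.asarray(self.pivot_in_parent, dtype=float).reshape(2)
        if self.mass <= 0:
            raise ValueError(f"planar body {self.name!r}: mass must be positive")


def _rot(phi, r):
    """Apply R(phi) (CCW) to body-frame vector r=(2,); phi batched."""
    c, s = np.cos(phi), np.sin(phi)
    return np.stack([c * r[0] - s * r[1], s * r[0] + c * r[1]], axis=-1)


def _perp(v):
    """90-degree CCW rotation of (..., 2) vectors."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


class PlanarModel:
    """Tree of planar bodies; root is free (x, z, pitch), children revolute."""

    def __init__(self, bodies: list[PlanarBody], coordinate_names: list[str] | None = None,
                 gravity: float = GRAVITY):
        if not bodies or bodies[0].parent is not None:
            raise ValueError("first body must be the free root (parent None)")
        self.bodies = bodies
        self.body_index = {b.name: i for i, b in enumerate(bodies)}
        self.gravity = gravity
        for b in bodies[1:]:
            if b.parent not in self.body_index or self.body_index[b.parent] >= self.body_index[b.name]:
                raise ValueError(f"bodies must be in tree order; bad parent for {b.name!r}")
        # coordinates: [root_x, root_z, root_pitch, joint angles in body order]
        n = 3 + len(bodies) - 1
        if coordinate_names is None:
            coordinate_names = (["root_x", "root_z", "root_pitch"]
                                + [f"{b.name}_angle" for b in bodies[1:]])
        if len(coordinate_names) != n:
            raise ValueError("coordinate_names length mismatch")
        self.coordinate_names = list(coordinate_names)
        # angular coordinate index owned by each body (root owns pitch = 2)
        self._ang_coord = [2] + list(range(3, n))
        # path[b] = indices of angular coordinates on the chain root..body b
        self._path: list[list[int]] = []
        for i, b in enumerate(bodies):
            if i == 0:
                self._path.append([2])
            else:
                self._path.append(self._path[self.body_index[b.parent]] + [self._ang_coord[i]])

    @property
    def ndof(self) -> int:
        return 3 + len(self.bodies) - 1

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bodies))

    def coord_index(self, name: str) -> int:
        return self.coordinate_names.index(name)

    # -- kinematics ---------------------------------------------------------

    def kinematics(self, q, qd=None, qdd=None):
        """Recursively propagate frame origins/angles (and rates if given).

        Returns a dict with per-body arrays stacked on axis 0:
        ``phi, om, al, p, v, a`` (angles/rates and origin pos/vel/acc) plus
        ``pivot`` world positions per angular coordinate.
        """
        q = np.asarray(q)
        batch = q.shape[:-1]
        zeros2 = np.zeros(batch + (2,), dtype=q.dtype)
        if qd is None:
            qd = np.zeros_like(q)
        if qdd is None:
            qdd = np.zeros_like(np.asarray(qd))
        qd = np.asarray(qd)
        qdd = np.asarray(qdd)
        nb = len(self.bodies)
        phi = [None] * nb
        om = [None] * nb
        al = [None] * nb
        p = [None] * nb
        v = [None] * nb
        a = [None] * nb
        for i, b in enumerate(self.bodies):
            if i == 0:
                phi[i], om[i], al[i] = q[..., 2], qd[..., 2], qdd[..., 2]
                p[i] = np.stack([q[..., 0], q[..., 1]], axis=-1)
                v[i] = np.stack([qd[..., 0], qd[..., 1]], axis=-1)
                a[i] = np.stack([qdd[..., 0], qdd[..., 1]], axis=-1)
            else:
                ip = self.body_index[b.parent]
                j = self._ang_coord[i]
                r = _rot(phi[ip], b.pivot_in_parent)
                rp = _perp(r)
                p[i] = p[ip] + r
                v[i] = v[ip] + om[ip][..., None] * rp
                a[i] = a[ip] + al[ip][..., None] * rp - (om[ip] ** 2)[..., None] * r
                phi[i] = phi[ip] + q[..., j]
                om[i] = om[ip] + qd[..., j]
                al[i] = al[ip] + qdd[..., j]
        return {"phi": phi, "om": om, "al": al, "p": p, "v": v, "a": a}

    def point_state(self, kin, body: str, offset):
        """(p, v, a) of a body-fixed point given a kinematics evaluation."""
        i = self.body_index[body]
        offset = np.asarray(offset, dtype=float).reshape(2)
        r = _rot(kin["phi"][i], offset)
        rp = _perp(r)
        p = kin["p"][i] + r
        v = kin["v"][i] + kin["om"][i][..., None] * rp
        a = kin["a"][i] + kin["al"][i][..., None] * rp - (kin["om"][i] ** 2)[..., None] * r
        return p, v, a

    def com_states(self, kin):
        """Per-body COM position/velocity/acceleration lists."""
        out_p, out_v, out_a = [], [], []
        for b in self.bodies:
            p, v, a = self.point_state(kin, b.name, b.com_offset)
            out_p.append(p)
            out_v.append(v)
            out_a.append(a)
        return out_p, out_v, out_a

    # -- force mapping ------------------------------------------------------

    def _point_generalized(self, kin, body: str, point_world, force, torque=None):
        """Generalized force (..., n) of force (..., 2) + torque at a world point."""
        i = self.body_index[body]
        batch = np.broadcast_shapes(point_world.shape[:-1], force.shape[:-1])
        dtype = np.result_type(point_world.dtype, force.dtype)
        Q = np.zeros(batch + (self.ndof,), dtype=dtype)
        Q[..., 0] += force[..., 0]
        Q[..., 1] += force[..., 1]
        for j in self._path[i]:
            pivot = kin["p"][0] if j == 2 else kin["p"][self._ang_coord.index(j)]
            lever = _perp(point_world - pivot)
            Q[..., j] += np.sum(force * lever, axis=-1)
            if torque is not None:
                Q[..., j] += torque
        return Q

    def generalized_forces(self, kin, loads):
        """Sum generalized forces of ``loads``: (body, offset, force, torque)."""
        Q = 0.0
        for body, offset, force, torque in loads:
            p, _, _ = self.point_state(kin, body, offset)
            Q = Q + self._point_generalized(kin, body, p, np.asarray(force),
                                            torque if torque is not None else None)
        return Q

    def inverse_dynamics(self, q, qd, qdd, loads=()):
        """Generalized forces the internal actuation must supply.

        ``loads`` are external point loads (contact, drag); gravity is always
        included.  Returns (..., n).
        """
        kin = self.kinematics(q, qd, qdd)
        g = np.array([0.0, -self.gravity])
        Q = 0.0
        for i, b in enumerate(self.bodies):
            pc, _, ac = self.point_state(kin, b.name, b.com_offset)
            f_inert = b.mass * (ac - g)
            Q = Q + self._point_generalized(kin, b.name, pc, f_inert)
            n_inert = b.inertia * kin["al"][i]
            for j in self._path[i]:
                Q[..., j] += n_inert
        if loads:
            Q = Q - self.generalized_forces(kin, loads)
        return Q

    def mass_matrix(self, q):
        """M(q) via inverse dynamics with unit accelerations (gravity removed)."""
        q = np.asarray(q, dtype=float)
        n = self.ndof
        qz = np.zeros(n)
        bias = self.inverse_dynamics(q, qz, qz)
        M = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            M[:, j] = self.inverse_dynamics(q, qz, e) - bias
        return M

    def bias_forces(self, q, qd):
        """Velocity-dependent + gravity generalized forces: ID(q, qd, 0)."""
        return self.inverse_dynamics(q, qd, np.zeros_like(np.asarray(q)))


def planar_from_config(model) -> PlanarModel:
    """Project a 3D skier model (``MultibodyModel``) onto the sagittal plane.

    Moving joints must be the planar root plus y-axis revolutes; locked
    subtrees are lumped into their carrier (transverse-axis inertia, in-plane
    COM).  Contact points from the config's ``planar.contact_points`` section
    are attached to their carrier body with binding offsets composed in.
    """
    cfg = model.config
    root_joint = next(j for j in model._order if j.parent == "ground")
    if root_joint.kind != "planar3":
        raise ValueError("planar projection expects a planar3 root joint")

    lumped_into: dict[str, str] = {}    # welded segment -> carrier
    carriers = [root_joint.child]
    for j in model._order:
        if j.parent == "ground":
            continue
        if j.kind == "locked":
            carrier = j.parent
            while carrier in lumped_into:
                carrier = lumped_into[carrier]
            lumped_into[j.child] = carrier
        elif j.kind == "revolute1":
            if abs(abs(j.axis[1]) - 1.0) > 1e-9:
                raise ValueError(f"joint {j.name!r}: planar model needs y-axis revolutes")
            carriers.append(j.child)
        else:
            raise ValueError(f"joint {j.name!r}: kind {j.kind!r} not representable in-plane")

    def proj(v3):
        return np.array([v3[0], v3[2]])

    # offsets of welded segments relative to their carrier origin (q=0 kinematics)
    poses = model.forward_kinematics(np.zeros(model.ndof))

    bodies = []
    coord_names = []
    for seg_name in carriers:
        seg = model.segments[seg_name]
        joint = model.joints[seg.parent_joint]
        m, com, inertia = model.lumped_mass_properties(seg_name)
        p_seg, R_seg = poses[seg_name]
        if joint.parent == "ground":
            parent, pivot = None, np.zeros(2)
        else:
            parent = joint.parent
            while parent in lumped_into:
                parent = lumped_into[parent]
            # q=0 poses are pure translations, so parent-frame == world offsets
            pivot = proj(p_seg - poses[parent][0])
        coord_names += joint.coordinate_names()
        bodies.append(PlanarBody(
            name=seg_name, mass=m, inertia=float(inertia[1, 1]),
            com_offset=proj(com), parent=parent, pivot_in_parent=pivot,
        ))
    # axis sign: a y-axis revolute with angle q rotates about +y (3D), which is
    # clockwise in the x-z plane; the planar engine is CCW about the out-of-plane
    # axis. Both presets use +y axes, so q maps 1:1 onto the CCW planar angle
    # with the out-of-plane axis taken as -y. This fixes the sign convention:
    # positive hip coordinate = CCW in (x, z) = thigh swinging toward +x.
    pm = PlanarModel(bodies, coordinate_names=coord_names)

    # attach configured contact points (offsets relative to their 3D body,
    # recomposed relative to the planar carrier)
    for cp in cfg.get("planar", {}).get("contact_points", []):
        body3 = cp["body"]
        carrier = body3
        while carrier in lumped_into:
            carrier = lumped_into[carrier]
        off3 = np.array([cp["offset"][0], 0.0, cp["offset"][1]])
        p_b, R_b = poses[body3]
        p_c, R_c = poses[carrier]
        off_carrier = R_c.T @ (p_b + R_b @ off3 - p_c)
        pm.bodies[pm.body_index[carrier]].points[cp["name"]] = proj(off_carrier)
    return pm
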