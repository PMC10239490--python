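"""Segmented ski and environment forces.

The ski is a chain of rigid segments joined by revolute spring-damper joints
whose unloaded equilibrium reproduces the camber arc.  Snow contact applies
three force components per loaded segment: a penetration force normal to the
surface following a hypoplastic (loading-history dependent) law, a shear force
orthogonal to the ski edge resisting lateral skidding, and Coulomb friction
antiparallel to the segment velocity.  Air drag acts on the skier's pelvis COM.

The hypoplastic law is a two-branch incremental stiffness model: virgin
loading follows ``k_load * depth``; unloading/reloading below the maximum
compressed depth follows a stiffer slope anchored at the memory point, so snow
that was compressed once offers less resistance on re-penetration at the same
depth (the groove-forming behavior: the ski tail follows the groove cut by the
tip).  The memory depth is explicit state, advanced with the discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._smooth import smooth_max, smooth_pos, unit_regularized
from .planar import PlanarBody, PlanarModel


@dataclass
class SkiSpec:
    n_segments: int = 18
    length: float = 1.70            # m, total
    mass: float = 3.40              # kg, total
    width: float = 0.07             # m
    camber_height: float = 0.006    # m, unloaded arch height at mid-ski
    side_cut_radius: float = 18.0   # m
    bend_stiffness: float = 260.0   # N*m/rad per inter-segment joint
    bend_damping: float = 1.2       # N*m*s/rad

    def __post_init__(self):
        if self.n_segments < 2:
            raise ValueError("ski needs at least 2 segments")
        if self.bend_stiffness < 0 or self.bend_damping < 0:
            raise ValueError("stiffness/damping must be nonnegative")
        if self.side_cut_radius <= 0:
            raise ValueError("side-cut radius must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "SkiSpec":
        return cls(
            n_segments=cfg.get("n_segments", 18), length=cfg.get("length_m", 1.70),
            mass=cfg.get("mass_kg", 3.40), width=cfg.get("width_m", 0.07),
            camber_height=cfg.get("camber_height_m", 0.006),
            side_cut_radius=cfg.get("side_cut_radius_m", 18.0),
            bend_stiffness=cfg.get("bend_stiffness", 260.0),
            bend_damping=cfg.get("bend_damping", 1.2),
        )

    @property
    def segment_length(self) -> float:
        return self.length / self.n_segments

    @property
    def segment_mass(self) -> float:
        return self.mass / self.n_segments

    def camber_angles(self) -> np.ndarray:
        """Unloaded relative joint angles reproducing the camber arc.

        A circular arc of chord L and sagitta h turns by 8h/L in total; that
        turning is spread uniformly over the inter-segment joints.
        """
        total_turn = 8.0 * self.camber_height / self.length
        return np.full(self.n_segments - 1, -total_turn / (self.n_segments - 1))

    def side_cut_half_width(self, xi) -> np.ndarray:
        """Half-width of the ski at longitudinal station xi (m from center).

        The edge follows a circular arc of the side-cut radius: the waist is
        narrower than tip/tail by the arc sagitta.
        """
        R = self.side_cut_radius
        sag_max = R - np.sqrt(R**2 - (self.length / 2.0) ** 2)
        sag = R - np.sqrt(R**2 - np.asarray(xi) ** 2)
        return self.width / 2.0 + (sag - sag_max)


@dataclass
class SnowSurface:
    """Snow surface z = s(x, y) plus hardness parameters of the penetration law."""

    height: Callable[[np.ndarray, np.ndarray], np.ndarray]
    k_load: float = 90000.0          # N/m, virgin-loading stiffness per contact point
    stiffness_ratio: float = 4.0     # unload/reload slope = ratio * k_load
    rate_damping: float = 3000.0     # N*s/m
    shear_coefficient: float = 60000.0  # N per m of depth
    edging_softening: float = 0.5    # stiffness reduction factor at full edging

    def __post_init__(self):
        if self.k_load <= 0 or self.stiffness_ratio < 1.0:
            raise ValueError("need k_load > 0 and unloading stiffness >= loading stiffness")

    @classmethod
    def inclined_plane(cls, slope_angle_deg: float, **params) -> "SnowSurface":
        """Planar slope dropping in +x: z = -tan(slope)*x."""
        t = np.tan(np.deg2rad(slope_angle_deg))
        surf = cls(height=lambda x, y: -t * x, **params)
        surf.slope_angle = np.deg2rad(slope_angle_deg)
        return surf

    @classmethod
    def from_config(cls, cfg: dict) -> "SnowSurface":
        return cls.inclined_plane(
            cfg.get("slope_angle_deg", 12.3),
            k_load=cfg.get("k_load", 90000.0),
            stiffness_ratio=cfg.get("stiffness_ratio", 4.0),
            rate_damping=cfg.get("rate_damping", 3000.0),
            shear_coefficient=cfg.get("shear_coefficient", 60000.0),
        )

    def normal(self, x, y, h: float = 1e-6) -> np.ndarray:
        """Unit upward surface normal by central differences of the height."""
        dzdx = (self.height(x + h, y) - self.height(x - h, y)) / (2 * h)
        dzdy = (self.height(x, y + h) - self.height(x, y - h)) / (2 * h)
        n = np.stack(np.broadcast_arrays(-dzdx, -dzdy, np.ones_like(np.asarray(dzdx, dtype=float))), axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass
class ContactKinematics:
    penetration_depth: float         # m, >= 0 in contact
    penetration_rate: float          # m/s, positive = penetrating
    edging_angle: float              # rad
    edge_direction: np.ndarray       # unit 3-vector along the loaded edge
    segment_velocity: np.ndarray     # m/s, 3-vector
    surface_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


@dataclass
class ContactState:
    """Hypoplastic memory: maximum compressed depth per ski segment."""

    max_compressed_depth: np.ndarray

    def __post_init__(self):
        self.max_compressed_depth = np.asarray(self.max_compressed_depth, dtype=float)
        if np.any(self.max_compressed_depth < 0):
            raise ValueError("memory depth must be nonnegative")


@dataclass
class AeroParams:
    cda: float = 0.3                # m^2
    rho: float = 1.07               # kg/m^3
    wind: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.cda < 0 or self.rho <= 0:
            raise ValueError("need CdA >= 0 and rho > 0")
        self.wind = np.asarray(self.wind, dtype=float)


# ---------------------------------------------------------------------------
# ski chain

def build_ski(spec: SkiSpec):
    """(planar chain model, passive joint moment function) for one ski.

    The chain has ``n_segments`` bodies and ``n_segments - 1`` spring-damper
    revolute joints; the moment function maps relative joint angles and rates
    to ``-k*(theta - theta_camber) - c*thetadot``, so the unloaded equilibrium
    is the camber arc.
    """
    L, m = spec.segment_length, spec.segment_mass
    I_seg = m * L**2 / 12.0
    bodies = [PlanarBody("seg0", m, I_seg, [L / 2.0, 0.0])]
    for i in range(1, spec.n_segments):
        bodies.append(PlanarBody(f"seg{i}", m, I_seg, [L / 2.0, 0.0],
                                 parent=f"seg{i-1}", pivot_in_parent=[L, 0.0]))
    chain = PlanarModel(bodies)
    theta_camber = spec.camber_angles()

    def passive_moments(joint_angles, joint_rates):
        return (-spec.bend_stiffness * (np.asarray(joint_angles) - theta_camber)
                - spec.bend_damping * np.asarray(joint_rates))

    return chain, passive_moments


# ---------------------------------------------------------------------------
# force components

def hypoplastic_normal_force(depth, rate, memory, k_load, stiffness_ratio, rate_damping):
    """Scalar/batched hypoplastic penetration force; complex-step safe.

    Elastic part: min(virgin slope ``k_load*d``, unload/reload branch anchored
    at the memory depth with slope ``stiffness_ratio*k_load``), floored at
    zero.  The rate term adds dissipation, gated smoothly to contact, and the
    total is floored at zero.
    """
    d = smooth_pos(depth, 1e-9)
    virgin = k_load * d
    branch = smooth_pos(k_load * memory - stiffness_ratio * k_load * (memory - d))
    elastic = -smooth_max(-virgin, -branch)          # smooth min of the two slopes
    gate = d / (d + 2e-3)
    return smooth_pos(elastic + rate_damping * rate * gate)


def penetration_force(kin: ContactKinematics, state: ContactState, surf: SnowSurface,
                      index=slice(None)):
    """(normal force magnitude N, updated ContactState).

    Edging reduces the effective stiffness (a set ski edge cuts with less base
    area).  Memory advances to max(memory, depth).
    """
    mem = state.max_compressed_depth[index]
    k = surf.k_load * (1.0 - surf.edging_softening * np.sin(abs(kin.edging_angle)))
    force = hypoplastic_normal_force(kin.penetration_depth, kin.penetration_rate, mem,
                                     k, surf.stiffness_ratio, surf.rate_damping)
    new_mem = np.array(state.max_compressed_depth, copy=True)
    new_mem[index] = np.real(smooth_max(mem, smooth_pos(kin.penetration_depth)))
    return force, ContactState(new_mem)


def shear_force(kin: ContactKinematics, shear_coefficient: float,
                slip_epsilon: float = 1e-3) -> np.ndarray:
    """Lateral-skid resistance: proportional to depth, orthogonal to the edge.

    Acts within the surface tangent plane along the lateral (edge-orthogonal)
    direction, opposing the lateral velocity component, with a saturated
    viscous regularization near zero slip.
    """
    if shear_coefficient < 0:
        raise ValueError("shear coefficient must be nonnegative")
    d = smooth_pos(kin.penetration_depth)
    n = np.asarray(kin.surface_normal, dtype=float)
    e = np.asarray(kin.edge_direction, dtype=float)
    lat = np.cross(n, e)
    lat = lat / np.linalg.norm(lat)
    v_lat = np.dot(np.asarray(kin.segment_velocity, dtype=float), lat)
    sat = v_lat / np.sqrt(v_lat**2 + slip_epsilon**2)
    return -shear_coefficient * d * sat * lat


def friction_force(normal_force, segment_velocity, mu: float = 0.08,
                   slip_epsilon: float = 1e-3):
    """Coulomb friction, antiparallel to the segment velocity, smooth at v=0."""
    v = np.asarray(segment_velocity)
    return -mu * normal_force * unit_regularized(v, slip_epsilon)


def air_drag(com_velocity, params: AeroParams):
    """Quadratic drag 0.5*rho*CdA*|v_rel|^2, antiparallel to the relative wind."""
    v_rel = np.asarray(com_velocity) - params.wind
    speed = np.sqrt(np.sum(v_rel * v_rel, axis=-1, keepdims=True))
    return -0.5 * params.rho * params.cda * speed * v_rel


def edge_contact_kinematics(position, rotation, velocity, angular_velocity,
                            surf: SnowSurface, spec: SkiSpec, station: float = 0.0,
                            roll_sign: float = 1.0) -> ContactKinematics:
    """Contact kinematics of the loaded edge point of one ski segment (3D).

    ``position``/``rotation`` give the segment frame (x along the ski, z up
    off the base); the loaded edge point sits at the side-cut lateral profile
    at longitudinal ``station``, on the side selected by ``roll_sign``.
    The edging angle is the angle between the ski base plane and the surface
    tangent plane; depth is measured along the surface normal and clamped at 0.
    """
    p = np.asarray(position, dtype=float)
    R = np.asarray(rotation, dtype=float)
    v = np.asarray(velocity, dtype=float)
    w = np.asarray(angular_velocity, dtype=float)
    half_width = spec.side_cut_half_width(station)
    edge_local = np.array([station, roll_sign * half_width, 0.0])
    p_edge = p + R @ edge_local
    v_edge = v + np.cross(w, R @ edge_local)
    n_surf = surf.normal(p_edge[0], p_edge[1])
    n_base = R @ np.array([0.0, 0.0, 1.0])
    cos_e = np.clip(np.dot(n_surf, n_base), -1.0, 1.0)
    edging = np.arccos(cos_e)
    gap = np.dot(n_surf, p_edge - np.array([p_edge[0], p_edge[1], surf.height(p_edge[0], p_edge[1])]))
    depth = max(-gap, 0.0)
    rate = -np.dot(n_surf, v_edge) if depth > 0 else 0.0
    edge_dir = R @ np.array([1.0, 0.0, 0.0])
    edge_dir = edge_dir - np.dot(edge_dir, n_surf) * n_surf
    nrm = np.linalg.norm(edge_dir)
    edge_dir = edge_dir / nrm if nrm > 1e-12 else np.array([1.0, 0.0, 0.0])
    return ContactKinematics(
        penetration_depth=float(depth), penetration_rate=float(rate),
        edging_angle=float(edging), edge_direction=edge_dir,
        segment_velocity=v_edge, surface_normal=n_surf,
    )
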