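"""Intersegmental knee loads and the data-driven three-plane ACL force model.

Sagittal-plane knee loads come from a Newton-Euler recursion over the distal
chain (ski -> foot -> shank): the net force/moment transmitted across the
knee equals the inertial-minus-applied resultant of everything below it,
expressed in the tibia anatomical frame (x anterior, z proximal along the
shank).  Frontal- and transverse-plane knee moments, which a sagittal model
cannot produce, are supplied by the carved-turn overlay: the centripetal
ground-reaction force of the loaded edge passes laterally to the knee and
creates an external abduction moment on the outside leg (adduction on the
inside leg).

The ACL force is the sum of three components:

* sagittal — a flexion-dependent proportion of the anterior ligamentous
  shear force (intersegmental shear minus muscle contributions: hamstrings
  and gastrocnemius pull the tibia posteriorly, the quadriceps act through
  the patellar tendon whose angle changes sign around ~70 degrees flexion);
* frontal — an exponential function of the external abduction moment,
  decaying with knee flexion, zero for adduction-side moments;
* transverse — the analogous exponential in the internal-rotation moment.

Coefficients ship in an editable file with synthetic literature-informed
defaults; absolute ACL values are therefore coefficient-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import load_acl_coefficients
from .dynamics import SkierSystem, Trajectory

GRAV = 9.81


@dataclass
class KneeModelCoefficients:
    sagittal_flexion_deg: np.ndarray
    sagittal_proportion: np.ndarray
    frontal_scale: float
    frontal_moment_rate: float
    frontal_flexion_rate: float
    transverse_scale: float
    transverse_moment_rate: float
    transverse_flexion_rate: float
    pt_flexion_deg: np.ndarray
    pt_angle_deg: np.ndarray
    muscle_lines: dict

    def __post_init__(self):
        if np.any((self.sagittal_proportion < 0) | (self.sagittal_proportion > 1)):
            raise ValueError("sagittal proportion must lie in [0, 1]")
        if min(self.frontal_scale, self.transverse_scale) < 0:
            raise ValueError("component scales must be nonnegative")

    @classmethod
    def from_config(cls, cfg: dict | str | None = None) -> "KneeModelCoefficients":
        if cfg is None or isinstance(cfg, str):
            cfg = load_acl_coefficients(cfg or "acl_coefficients")
        sp = cfg["sagittal_proportion"]
        fr = cfg["frontal"]
        tr = cfg["transverse"]
        pt = cfg["patellar_tendon_angle"]
        return cls(
            sagittal_flexion_deg=np.asarray(sp["flexion_deg"], dtype=float),
            sagittal_proportion=np.asarray(sp["proportion"], dtype=float),
            frontal_scale=fr["scale_n"], frontal_moment_rate=fr["moment_rate"],
            frontal_flexion_rate=fr["flexion_rate"],
            transverse_scale=tr["scale_n"], transverse_moment_rate=tr["moment_rate"],
            transverse_flexion_rate=tr["flexion_rate"],
            pt_flexion_deg=np.asarray(pt["flexion_deg"], dtype=float),
            pt_angle_deg=np.asarray(pt["angle_deg"], dtype=float),
            muscle_lines=cfg.get("knee_muscle_lines", {}),
        )

    def proportion(self, flexion_rad):
        """ACL share of the anterior shear vs flexion; clamped outside the table."""
        return np.interp(np.rad2deg(np.asarray(flexion_rad)),
                         self.sagittal_flexion_deg, self.sagittal_proportion)

    def patellar_tendon_angle(self, flexion_rad):
        """Patellar-tendon angle (rad, anterior positive) vs knee flexion."""
        return np.deg2rad(np.interp(np.rad2deg(np.asarray(flexion_rad)),
                                    self.pt_flexion_deg, self.pt_angle_deg))


def _leg_bodies(system: SkierSystem, leg: str):
    if leg not in ("left", "right"):
        raise ValueError("leg must be 'left' or 'right'")
    s = "r" if leg == "right" else "l"
    distal = [n for n in (f"tibia_{s}", f"foot_{s}", f"ski_{s}")
              if n in system.plane.body_index]
    return s, distal


def intersegmental_loads(system: SkierSystem, traj: Trajectory, leg: str = "right",
                         defect_warn_tol: float = 1e-5) -> pd.DataFrame:
    """Knee intersegmental force/moment series in the tibia frame.

    Newton-Euler recursion over the distal chain {shank, foot, ski} with the
    contact forces recomputed from the trajectory states.  Columns:
    anterior shear (N, + pushes the tibia forward), compression (N, +),
    flexion moment (N*m, + flexes), plus the knee flexion angle (rad).
    Accelerations use the same backward differences as the implicit-Euler
    discretization.
    """
    side, distal = _leg_bodies(system, leg)
    q, qd, s_m, a, mem = system.split(traj.states)
    h = traj.h
    # backward-difference accelerations, consistent with the stepper
    qdd = np.zeros_like(qd)
    qdd[1:] = (qd[1:] - qd[:-1]) / h
    qdd[0] = qdd[1]
    defects = system.defect(traj.states[:-1], traj.states[1:], traj.controls[1:], h)
    maxdef = float(np.max(np.abs(defects)))
    if maxdef > defect_warn_tol:
        import warnings
        warnings.warn(f"trajectory dynamics violation {maxdef:.2e} exceeds {defect_warn_tol:.0e}; "
                      "knee loads may be inconsistent", stacklevel=2)

    kin = system.plane.kinematics(q, qd, qdd)
    _, _, _, loads = system.contact_terms(kin, q, mem)
    ext_by_body: dict[str, list] = {}
    for (body, off, force, _), cp in zip(loads, system.contact_points):
        ext_by_body.setdefault(body, []).append((off, force))

    knee_joint = f"knee_{side}"
    # knee center = tibia origin
    p_knee, v_knee, _ = system.plane.point_state(kin, f"tibia_{side}", [0.0, 0.0])
    F = np.zeros(q.shape[:-1] + (2,))
    M = np.zeros(q.shape[:-1])
    g = np.array([0.0, -system.plane.gravity])
    for name in distal:
        b = system.plane.bodies[system.plane.body_index[name]]
        pc, _, ac = system.plane.point_state(kin, name, b.com_offset)
        i = system.plane.body_index[name]
        F += b.mass * (ac - g)
        r = pc - p_knee
        M += r[..., 0] * (b.mass * (ac - g))[..., 1] - r[..., 1] * (b.mass * (ac - g))[..., 0]
        M += b.inertia * kin["al"][i]
        for off, force in ext_by_body.get(name, []):
            pf, _, _ = system.plane.point_state(kin, name, off)
            F -= force
            rf = pf - p_knee
            M -= rf[..., 0] * force[..., 1] - rf[..., 1] * force[..., 0]

    # tibia frame: z along shank (knee->ankle is -z), x anterior.
    # F is the force the femur transmits to the distal chain; the anterior
    # shear is reported as the DEMAND on the knee-crossing structures:
    # positive = the environment/inertia push the tibia anteriorly relative
    # to the femur, i.e. the direction that loads the ACL.
    i_tib = system.plane.body_index[f"tibia_{side}"]
    phi = kin["phi"][i_tib]
    c, s = np.cos(phi), np.sin(phi)
    f_anterior = -(c * F[..., 0] + s * F[..., 1])
    f_axial = -s * F[..., 0] + c * F[..., 1]
    flexion = -q[..., system.plane.coord_index(f"{knee_joint}_angle")]
    return pd.DataFrame({
        "time": traj.times,
        "anterior_shear": f_anterior,
        "compression": f_axial,
        "flexion_moment": -M,   # internal convention: + = flexes the knee
        "knee_flexion": flexion,
    })


def ligamentous_shear(inter: pd.DataFrame, muscle_forces: dict[str, np.ndarray],
                      coeffs: KneeModelCoefficients) -> np.ndarray:
    """Anteroposterior shear demand on the passive structures (anterior +, N).

    Adds the anterior components of the knee-crossing muscle forces acting on
    the tibia to the intersegmental anterior-shear demand: quadriceps pull
    the tibia anteriorly through the patellar tendon at low flexion (angle
    table vs flexion, sign change near 70 degrees), hamstrings and
    gastrocnemius pull it posteriorly and unload the ACL.
    """
    flexion = inter["knee_flexion"].to_numpy()
    shear = inter["anterior_shear"].to_numpy().copy()
    for name, force in muscle_forces.items():
        base = name.rsplit("_", 1)[0]
        if base not in coeffs.muscle_lines:
            raise ValueError(f"no line-of-action entry for knee muscle {name!r}")
        entry = coeffs.muscle_lines[base]
        if entry.get("patellar_tendon"):
            comp = np.sin(coeffs.patellar_tendon_angle(flexion))
        else:
            comp = entry["anterior_component"]
        shear = shear + np.asarray(force) * comp
    return shear


@dataclass
class ACLComponents:
    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.sagittal + self.frontal + self.transverse

    def as_frame(self, times) -> pd.DataFrame:
        return pd.DataFrame({"time": times, "sagittal": self.sagittal,
                             "frontal": self.frontal, "transverse": self.transverse,
                             "total": self.total})


def acl_force(lig_shear, abduction_moment, internal_rotation_moment, flexion,
              coeffs: KneeModelCoefficients) -> ACLComponents:
    """Three-plane ACL force (N, each component >= 0).

    ``abduction_moment``: external abduction positive (ACL-loading side);
    adduction-side (negative) values contribute nothing.  Analogous for the
    internal-rotation moment.
    """
    lig_shear = np.asarray(lig_shear, dtype=float)
    m_ab = np.asarray(abduction_moment, dtype=float)
    m_ir = np.asarray(internal_rotation_moment, dtype=float)
    flexion = np.asarray(flexion, dtype=float)
    sag = coeffs.proportion(flexion) * np.maximum(lig_shear, 0.0)
    fro = (coeffs.frontal_scale
           * (np.exp(coeffs.frontal_moment_rate * np.maximum(m_ab, 0.0)) - 1.0)
           * np.exp(-coeffs.frontal_flexion_rate * flexion))
    tra = (coeffs.transverse_scale
           * (np.exp(coeffs.transverse_moment_rate * np.maximum(m_ir, 0.0)) - 1.0)
           * np.exp(-coeffs.transverse_flexion_rate * flexion))
    return ACLComponents(sagittal=np.broadcast_to(sag, lig_shear.shape).copy() * 1.0,
                         frontal=np.broadcast_to(fro, lig_shear.shape).copy() * 1.0,
                         transverse=np.broadcast_to(tra, lig_shear.shape).copy() * 1.0)


def body_weight_normalize(force, subject_mass_kg: float):
    """Force in multiples of body weight (BW = m * g)."""
    if subject_mass_kg <= 0:
        raise ValueError("subject mass must be positive")
    return np.asarray(force) / (subject_mass_kg * GRAV)


def overlay_knee_moments(system: SkierSystem, traj: Trajectory, overlay,
                         leg: str = "right") -> pd.DataFrame:
    """Frontal/transverse knee moments from the carved-turn lateral overlay.

    The per-leg share of the centripetal edge force passes a few centimeters
    lateral to the knee center (overlay moment arms): external abduction on
    the outside (right) knee, adduction (negative) on the inside knee, plus a
    small internal-rotation moment on the tibia.
    """
    _leg_bodies(system, leg)    # validates the leg label
    q, qd, *_ = system.split(traj.states)
    speed = np.hypot(qd[:, 0], qd[:, 1])
    f_lat_total = overlay.lateral_force(traj.times, speed, system.plane.total_mass)
    share = overlay.outside_share(traj.times)
    f_leg = f_lat_total * (share if leg == "right" else (1.0 - share))
    m_frontal = f_leg * overlay.frontal_moment_arm * (1.0 if leg == "right" else -1.0)
    m_ir = f_leg * overlay.transverse_moment_arm
    return pd.DataFrame({"time": traj.times, "abduction_moment": m_frontal,
                         "internal_rotation_moment": m_ir, "lateral_force": f_leg})


def knee_muscle_forces(system: SkierSystem, traj: Trajectory, leg: str,
                       coeffs: KneeModelCoefficients) -> dict[str, np.ndarray]:
    """Tendon forces of the knee-crossing muscles along the trajectory."""
    side, _ = _leg_bodies(system, leg)
    q, qd, s, a, _ = system.split(traj.states)
    sdot = np.zeros_like(s)
    sdot[1:] = (s[1:] - s[:-1]) / traj.h
    _, f_t, _ = system.muscle_torques(q, s, sdot, a)
    out = {}
    for i, name in enumerate(system.muscles.names):
        base = name.rsplit("_", 1)[0]
        if name.endswith(f"_{side}") and base in coeffs.muscle_lines:
            out[name] = f_t[:, i]
    return out


def knee_pipeline(system: SkierSystem, traj: Trajectory, overlay, leg: str = "right",
                  coeffs: KneeModelCoefficients | None = None) -> pd.DataFrame:
    """Full chain: recursion -> ligamentous shear -> three-plane ACL force."""
    coeffs = coeffs or KneeModelCoefficients.from_config()
    inter = intersegmental_loads(system, traj, leg)
    mus = knee_muscle_forces(system, traj, leg, coeffs)
    lig = ligamentous_shear(inter, mus, coeffs)
    mom = overlay_knee_moments(system, traj, overlay, leg)
    comp = acl_force(lig, mom["abduction_moment"].to_numpy(),
                     mom["internal_rotation_moment"].to_numpy(),
                     inter["knee_flexion"].to_numpy(), coeffs)
    out = comp.as_frame(traj.times)
    out["ligamentous_shear"] = lig
    out["abduction_moment"] = mom["abduction_moment"]
    out["internal_rotation_moment"] = mom["internal_rotation_moment"]
    out["knee_flexion"] = inter["knee_flexion"]
    out["anterior_shear"] = inter["anterior_shear"]
    out["compression"] = inter["compression"]
    out["flexion_moment"] = inter["flexion_moment"]
    out["total_bw"] = body_weight_normalize(
        out["total"].to_numpy(), system.config.get("subject", {}).get("mass_kg", 72.0))
    return out
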