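"""Synthetic study data: course geometry, a dynamically consistent reference
turn, measurement noise, and surface-EMG envelopes.

No motion-capture data ships with the package; everything the original
experiment measured is emulated here.  The reference turn is produced by
rolling out the muscle-driven skier under a posture-schedule controller
(:class:`skiturn.control.ExcitationPD`).  The applied excitations are recorded
per mesh node, so the stored trajectory satisfies the implicit system dynamics
exactly with its stored controls — it is a feasible point of the tracking
problem, with known ground truth.

The planar dynamics cover the sagittal motion; the carved-turn lateral motion
is a kinematic overlay (:class:`TurnOverlay`) built from the side-cut
geometry: the edging-angle schedule sets the carve radius ``R = R_sc *
cos(edging)``, the heading integrates the curvature, and the centripetal load
is shared between outside and inside leg.  The overlay supplies the track,
turn radius and the frontal/transverse knee moments that the planar dynamics
cannot produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .body import boot_moment
from .config import config_hash
from .control import ExcitationPD, PDGains, balance_com, glide_acceleration
from .dynamics import SkierSystem, Trajectory
from .ski_snow import SnowSurface


class GenerationError(RuntimeError):
    pass


@dataclass
class CourseSpec:
    slope_angle_deg: float = 12.3
    gate_offset_transverse: float = 8.0     # m
    gate_offset_downhill: float = 16.0      # m
    n_turns: int = 4

    def __post_init__(self):
        if not 0 < self.slope_angle_deg < 45:
            raise ValueError("slope angle must be in (0, 45) degrees")
        if self.gate_offset_transverse <= 0 or self.gate_offset_downhill <= 0:
            raise ValueError("gate offsets must be positive")


def generate_course(spec: CourseSpec, **snow_params):
    """(SnowSurface, gate positions (n_turns, 3)) on the inclined plane.

    Gates sit on the stated lattice: consecutive gates are one downhill
    offset apart and alternate sides of the fall line, one transverse offset
    apart.
    """
    surf = SnowSurface.inclined_plane(spec.slope_angle_deg, **snow_params)
    gates = np.zeros((spec.n_turns, 3))
    for k in range(spec.n_turns):
        gates[k, 0] = (k + 1) * spec.gate_offset_downhill
        gates[k, 1] = (spec.gate_offset_transverse / 2.0) * (-1) ** k
        gates[k, 2] = surf.height(gates[k, 0], gates[k, 1])
    return surf, gates


def _bump(t, t0, t1):
    """Smooth 0->1->0 cosine bump supported on (t0, t1)."""
    t = np.asarray(t, dtype=float)
    if t1 <= t0:
        return np.zeros_like(t)
    tc = np.clip(t, t0, t1)
    return np.where((t > t0) & (t < t1),
                    0.5 * (1 - np.cos(2 * np.pi * (tc - t0) / (t1 - t0))), 0.0)


@dataclass
class TurnOverlay:
    """Kinematic lateral description of the carved turn.

    ``edging(t)`` in rad, ``outside_share(t)`` in [0,1] (fraction of the load
    on the outside leg), and the side-cut radius define carve radius, heading
    and transverse displacement once a speed history is given.
    """

    steering_window: tuple[float, float] = (0.4, 1.6)
    max_edging_deg: float = 53.0
    outside_share_peak: float = 0.7
    side_cut_radius: float = 18.0
    # lateral miss distances of the leg's ground-reaction force line at the
    # knee center: the GRF passes a few cm lateral to the outside knee
    # (abduction) and spins the tibia slightly (internal rotation)
    frontal_moment_arm: float = 0.04      # m
    transverse_moment_arm: float = 0.01   # m

    def edging(self, t):
        return np.deg2rad(self.max_edging_deg) * _bump(t, *self.steering_window)

    def outside_share(self, t):
        return 0.5 + (self.outside_share_peak - 0.5) * _bump(t, *self.steering_window)

    def carve_radius(self, t):
        """Carving radius from side-cut geometry; inf outside the steering phase."""
        phi = np.asarray(self.edging(t))
        with np.errstate(divide="ignore"):
            return np.where(phi > 1e-6, self.side_cut_radius * np.cos(phi), np.inf)

    def lateral_path(self, times, speed):
        """(heading rad, transverse offset m) by integrating the curvature."""
        times = np.asarray(times)
        kappa = 1.0 / self.carve_radius(times)
        psi = np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1])
                                               * np.asarray(speed)[1:] * np.diff(times))])
        y = np.concatenate([[0.0], np.cumsum(np.sin(psi[1:]) * np.asarray(speed)[1:]
                                             * np.diff(times))])
        return psi, y

    def lateral_force(self, t, speed, total_mass):
        """Total centripetal force m*v^2/R during steering (N)."""
        R = self.carve_radius(t)
        return total_mass * np.asarray(speed) ** 2 / R


@dataclass
class ReferenceFixture:
    trajectory: Trajectory
    channels: pd.DataFrame          # time + tracked coordinates (SI units)
    excitations: pd.DataFrame       # ground-truth controls per node
    activations: pd.DataFrame       # ground-truth activations per node
    emg: pd.DataFrame               # synthetic EMG envelopes (scale-free)
    overlay: TurnOverlay
    seed: int
    manifest: dict = field(default_factory=dict)


# posture schedule parameters of the reference turn (rad); the crouch deepens
# during the steering phase while knee flexion stays above 60 degrees
_SCHED = {"hip0": 1.10, "hip_amp": 0.18, "knee0": 1.25, "knee_amp": 0.20}

_GAINS = PDGains(kp_hip=500, kd_hip=100, kp_knee=500, kd_knee=100,
                 kp_ankle=400, kd_ankle=30,
                 balance_gain=4.0, balance_rate_gain=0.5,
                 hip_balance_gain=2.0, hip_balance_rate_gain=0.3,
                 com_gain=6.0, com_rate_gain=1.5)


class ReferenceScheduler:
    """Quasi-static trim of the posture schedule.

    For each crouch level the ankle angle is solved so that the boot moment
    balances the center-of-pressure demand (with the downhill-acceleration
    pseudo-force included), and the pelvis pitch closes the leg chain so the
    skis stay parallel to the slope.
    """

    def __init__(self, system: SkierSystem, overlay: TurnOverlay,
                 v0: float = 11.0, sched: dict | None = None):
        self.system = system
        self.overlay = overlay
        self.v0 = v0
        self.sched = dict(_SCHED, **(sched or {}))
        self.names = system.plane.coordinate_names
        self.ix = {n: i for i, n in enumerate(self.names)}
        self.beta = system.slope_angle
        self.accel = glide_acceleration(system)
        self.w_normal = system.plane.total_mass * system.plane.gravity * np.cos(self.beta)
        grid = np.linspace(0.0, 1.0, 6)
        self._bgrid = grid
        self._ankles = np.array([self._solve_ankle(b) for b in grid])

    def posture(self, b: float, ankle: float) -> np.ndarray:
        s = self.sched
        hip = s["hip0"] + s["hip_amp"] * b
        knee = -(s["knee0"] + s["knee_amp"] * b)
        pitch = -self.beta - hip - knee - ankle
        q = np.zeros(self.system.n_q)
        q[self.ix["pelvis_pitch"]] = pitch
        for side in ("r", "l"):
            q[self.ix[f"hip_{side}_flexion"]] = hip
            q[self.ix[f"knee_{side}_angle"]] = knee
            q[self.ix[f"ankle_{side}_angle"]] = ankle
        return q

    def _com_rel_ankle(self, q) -> float:
        sysm = self.system
        kin = sysm.plane.kinematics(q)
        com = balance_com(sysm, kin, self.accel)
        p_ank = np.asarray(sysm.plane.point_state(kin, "tibia_r", [0.0, -0.43])[0])
        return float((com - p_ank) @ sysm._t_hat)

    def _solve_ankle(self, b: float) -> float:
        f = lambda ank: (boot_moment(ank, 0.0, self.system.boot)
                         + self._com_rel_ankle(self.posture(b, ank)) * self.w_normal / 2)
        return brentq(f, -0.4, 0.7)

    def q_des(self, t: float) -> np.ndarray:
        b = float(_bump(t, *self.overlay.steering_window))
        return self.posture(b, float(np.interp(b, self._bgrid, self._ankles)))

    def qd_des(self, t: float) -> np.ndarray:
        return (np.asarray(self.q_des(t + 0.01)) - np.asarray(self.q_des(max(t - 0.01, 0.0)))) / 0.02

    def initial_state(self) -> np.ndarray:
        """Statically balanced start: tail/tip penetration puts the CoP under
        the (acceleration-corrected) COM."""
        sysm = self.system
        q0 = self.q_des(0.0).copy()
        t_hat, n_hat = sysm._t_hat, sysm._n_hat
        kin = sysm.plane.kinematics(q0)
        pts = [np.asarray(sysm.plane.point_state(kin, b, o)[0]) for b, o, _ in sysm.contact_points]
        mid = sum(pts) / len(pts)
        com_t = float((balance_com(sysm, kin, self.accel) - mid) @ t_hat)
        t_tail = float((pts[0] - mid) @ t_hat)
        t_tip = float((pts[1] - mid) @ t_hat)
        Nt = np.linalg.solve([[1.0, 1.0], [t_tail, t_tip]],
                             [self.w_normal / 2, self.w_normal / 2 * com_t])
        d_tail, d_tip = np.clip(Nt, 20.0, None) / sysm.snow.k_load
        eps = (d_tail - d_tip) / (t_tip - t_tail)
        for side in ("r", "l"):
            q0[self.ix[f"ankle_{side}_angle"]] += eps
        kin = sysm.plane.kinematics(q0)
        gap_tail = float(np.asarray(
            sysm.plane.point_state(kin, *sysm.contact_points[0][:2])[0]) @ n_hat)
        q0[1] -= (gap_tail + d_tail) / n_hat[1]
        qd0 = np.zeros(sysm.n_q)
        qd0[0] = self.v0 * np.cos(self.beta)
        qd0[1] = -self.v0 * np.sin(self.beta)
        ctrl = ExcitationPD(sysm, self.q_des, gains=_GAINS)
        x_tmp = sysm.initial_state(q0, qd0)
        u0 = np.clip(ctrl(0.0, x_tmp), 0.0, 1.0)
        return sysm.initial_state(q0, qd0, a=u0)


def generate_reference_turn(system: SkierSystem | None = None, seed: int = 0,
                            T: float = 2.0, n_mesh: int = 75, v0: float = 11.0,
                            overlay: TurnOverlay | None = None,
                            settle_time: float = 1.2,
                            emg_noise_sd: float = 0.02) -> ReferenceFixture:
    """Forward-simulate the single carved-turn reference on the mesh.

    The rollout settles at the initial posture first (discarded), then runs
    the 2 s schedule at the mesh spacing, so collocation defects of the
    stored trajectory vanish identically.  Raises :class:`GenerationError`
    on a fall (pelvis dropping toward the snow) or solver failure.
    """
    system = system or SkierSystem()
    overlay = overlay or TurnOverlay(side_cut_radius=system.config.get("ski", {})
                                     .get("side_cut_radius_m", 18.0))
    sched = ReferenceScheduler(system, overlay, v0=v0)
    h = T / (n_mesh - 1)
    x = sched.initial_state()
    hold = ExcitationPD(system, lambda t: sched.q_des(0.0), gains=_GAINS)
    for k in range(int(round(settle_time / h))):
        sol = system.step(x, np.clip(hold(0.0, x), 0.0, 1.0), h)
        if not sol.success and np.max(np.abs(sol.fun)) > 1e-6:
            raise GenerationError(f"settling failed at step {k}")
        x = sol.x
    # restart at the origin, translated along the slope surface
    x = x.copy()
    x[1] += np.tan(system.slope_angle) * x[0]
    x[0] = 0.0

    ctrl = ExcitationPD(system, sched.q_des, qd_des_fn=sched.qd_des, gains=_GAINS)
    try:
        traj = system.forward_simulate(x, None, T, h, controller=ctrl)
    except Exception as exc:
        raise GenerationError(f"reference rollout failed: {exc}") from exc

    q, qd, s, a, mem = system.split(traj.states)
    n_hat = system._n_hat
    pelvis_height = q[:, 0] * n_hat[0] + q[:, 1] * n_hat[1]
    if np.any(pelvis_height < 0.4):
        raise GenerationError("fall detected: pelvis height below threshold")

    names = system.plane.coordinate_names
    channels = pd.DataFrame({"time": traj.times})
    for j, n in enumerate(names):
        channels[n] = q[:, j]
    excitations = pd.DataFrame(traj.controls, columns=system.muscles.names)
    excitations.insert(0, "time", traj.times)
    activations = pd.DataFrame(a, columns=system.muscles.names)
    activations.insert(0, "time", traj.times)
    emg = synthesize_emg(activations, seed=seed, noise_sd=emg_noise_sd)
    manifest = {
        "seed": int(seed), "T": T, "n_mesh": int(n_mesh), "v0": v0,
        "config_hash": config_hash(system.config),
        "schedule": dict(_SCHED),
        "steering_window": list(overlay.steering_window),
    }
    return ReferenceFixture(trajectory=traj, channels=channels, excitations=excitations,
                            activations=activations, emg=emg, overlay=overlay,
                            seed=int(seed), manifest=manifest)


def add_measurement_noise(channels: pd.DataFrame, angle_sd_deg: float = 0.5,
                          position_sd: float = 0.02, seed: int = 0,
                          smooth: bool = False, spline_smoothing: float | None = None,
                          ) -> pd.DataFrame:
    """Gaussian measurement noise per sample; optional quintic-spline smoothing.

    Angle channels (anything that is not a pelvis translation) get
    ``angle_sd_deg`` (converted to rad); translations get ``position_sd`` (m).
    """
    if angle_sd_deg < 0 or position_sd < 0:
        raise ValueError("noise SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    out = channels.copy()
    t = channels["time"].to_numpy()
    for col in channels.columns:
        if col == "time":
            continue
        sd = position_sd if col in ("pelvis_x", "pelvis_z") else np.deg2rad(angle_sd_deg)
        y = channels[col].to_numpy() + rng.normal(0.0, sd, size=len(t)) * (sd > 0)
        if smooth:
            from scipy.interpolate import UnivariateSpline
            s = spline_smoothing if spline_smoothing is not None else len(t) * sd**2
            y = UnivariateSpline(t, y, k=5, s=s)(t)
        out[col] = y
    return out


# the ten surface-EMG muscles of the original protocol, mapped onto the
# reduced muscle set (frontal-plane muscles are proxied by the nearest
# sagittal group; proxies are marked in the mapping)
EMG_MUSCLE_MAP = {
    "tibialis_anterior": "tibialis_anterior_r",
    "gastrocnemius_medialis": "gastrocnemius_r",
    "vastus_medialis": "vasti_r",
    "rectus_femoris": "rectus_femoris_r",
    "vastus_lateralis": "vasti_r",
    "biceps_femoris_lh": "hamstrings_r",
    "semitendinosus": "hamstrings_r",
    "adductor_longus": "iliopsoas_r",      # proxy: no frontal-plane muscles in the planar set
    "gluteus_medius": "gluteus_maximus_r",  # proxy
    "gluteus_maximus": "gluteus_maximus_r",
}


def synthesize_emg(activations: pd.DataFrame, seed: int = 0, noise_sd: float = 0.02,
                   gain_range: tuple[float, float] = (0.5, 2.0),
                   mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Rectified noisy scaled copies of the ground-truth activations.

    EMG amplitude is scale-free, so each channel gets a random gain in
    ``gain_range``; downstream comparison re-scales to the maximum of the
    estimated activation, which removes the gain again.
    """
    mapping = mapping or EMG_MUSCLE_MAP
    rng = np.random.default_rng(seed + 1)
    out = pd.DataFrame({"time": activations["time"]})
    for emg_name, channel in mapping.items():
        if channel not in activations.columns:
            raise ValueError(f"missing activation channel {channel!r} for EMG {emg_name!r}")
        gain = rng.uniform(*gain_range)
        trace = gain * activations[channel].to_numpy()
        trace = trace + rng.normal(0.0, noise_sd, size=len(trace))
        out[emg_name] = np.abs(trace)
    return out
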