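"""Excitation-space PD posture control and static muscle-redundancy mapping.

Used in two places: generating dynamically consistent reference motions (the
controller's applied excitations are recorded, so the resulting trajectory is
exactly muscle-consistent with its stored controls), and building the
PD-tracking initial guess for the collocation NLP.

The joint-torque demand is a PD law on desired joint angles; pelvis pitch is
unactuated and is stabilized by biasing the hip targets with the pitch error
(standing-balance strategy).  Torques are distributed over the muscles by a
least-norm solve on the effective torque capacities ``A[j, m] = arm * f_max``
(rigid-tendon approximation), then clipped to [0, 1] on top of a small
co-contraction bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class PDGains:
    kp_hip: float = 900.0
    kd_hip: float = 90.0
    kp_knee: float = 900.0
    kd_knee: float = 90.0
    kp_ankle: float = 350.0
    kd_ankle: float = 35.0
    # fore-aft balance: bias the ankle targets (center-of-pressure strategy)
    # with the pelvis pitch error; positive pitch = backward lean, countered
    # by pressing the ski tails (dorsiflexion torque)
    balance_gain: float = 1.5      # ankle-target bias per rad of pitch error
    balance_rate_gain: float = 0.5
    # hip strategy: pitched back -> flex the hips to bring the trunk forward
    hip_balance_gain: float = 1.5
    hip_balance_rate_gain: float = 0.5
    # direct COM feedback: ankle/hip target bias per m of COM offset error
    # (positive offset = COM too far forward -> plantarflex, extend hips)
    com_gain: float = 4.0
    com_rate_gain: float = 1.0
    cocontraction: float = 0.02


def glide_acceleration(system, speed: float = 12.0) -> float:
    """Estimated slope-tangential acceleration of steady gliding (m/s^2)."""
    g = system.plane.gravity
    beta = system.slope_angle
    drag = 0.5 * system.aero.rho * system.aero.cda * speed**2
    return g * np.sin(beta) - system.mu * g * np.cos(beta) - drag / system.plane.total_mass


def balance_com(system, kin, tangential_accel: float = 0.0):
    """Whole-body COM, shifted for the downhill-acceleration pseudo-force.

    A skier accelerating along the slope balances about the point where the
    resultant of gravity and the inertial pseudo-force crosses the surface;
    equivalently the static COM shifted backward by (a_t/g_n) * height.
    """
    t_hat, n_hat = system._t_hat, system._n_hat
    m_tot = system.plane.total_mass
    com = sum(b.mass * np.asarray(system.plane.point_state(kin, b.name, b.com_offset)[0])
              for b in system.plane.bodies) / m_tot
    g_n = system.plane.gravity * np.cos(system.slope_angle)
    base = sum(np.asarray(system.plane.point_state(kin, b, o)[0])
               for b, o, _ in system.contact_points) / len(system.contact_points)
    height = float((com - base) @ n_hat)
    return com - t_hat * (tangential_accel / g_n) * height


def support_loads(system, q, total_normal_force, tangential_accel: float = 0.0):
    """Static contact loads at the ski points with the CoP under the COM.

    Per ski, the tail/tip split solves force and moment balance about the
    (acceleration-corrected) whole-body COM; forces are floored at zero.
    Returns planar point loads usable by inverse dynamics.
    """
    kin = system.plane.kinematics(np.asarray(q, dtype=float))
    t_hat, n_hat = system._t_hat, system._n_hat
    com = balance_com(system, kin, tangential_accel)
    pts = [np.asarray(system.plane.point_state(kin, b, o)[0]) for b, o, _ in system.contact_points]
    loads = []
    n_skis = len(pts) // 2
    for s in range(n_skis):
        p_tail, p_tip = pts[2 * s], pts[2 * s + 1]
        t_tail = float((p_tail - com) @ t_hat)
        t_tip = float((p_tip - com) @ t_hat)
        share = total_normal_force / n_skis
        denom = t_tip - t_tail
        n_tail = share * t_tip / denom if abs(denom) > 1e-9 else share / 2
        n_tail = min(max(n_tail, 0.0), share)
        n_tip = share - n_tail
        for (body, off, _), f in zip(system.contact_points[2 * s:2 * s + 2],
                                     (n_tail, n_tip)):
            loads.append((body, off, f * n_hat, None))
    return loads


class ExcitationPD:
    """PD tracking of desired joint angles, mapped to muscle excitations."""

    def __init__(self, system, q_des_fn: Callable[[float], np.ndarray],
                 qd_des_fn: Callable[[float], np.ndarray] | None = None,
                 gains: PDGains | None = None):
        self.system = system
        self.q_des_fn = q_des_fn
        self.qd_des_fn = qd_des_fn or (lambda t: np.zeros(system.n_q))
        self.gains = gains or PDGains()
        names = system.plane.coordinate_names
        self.joint_idx = list(range(3, system.n_q))
        kp = np.zeros(system.n_q)
        kd = np.zeros(system.n_q)
        g = self.gains
        for j, n in enumerate(names):
            if "hip" in n:
                kp[j], kd[j] = g.kp_hip, g.kd_hip
            elif "knee" in n:
                kp[j], kd[j] = g.kp_knee, g.kd_knee
            elif "ankle" in n:
                kp[j], kd[j] = g.kp_ankle, g.kd_ankle
        self.kp, self.kd = kp, kd
        self._u = None
        self.integral_rate = 0.6   # fraction of the torque gap corrected per call
        self.leak = 0.97           # per-call decay of the integrated excitations
        self.tangential_accel = glide_acceleration(system)
        self.ankle_idx = [j for j, n in enumerate(names) if "ankle" in n]
        self.hip_idx = [j for j, n in enumerate(names) if "hip" in n]
        self.pitch_idx = names.index("pelvis_pitch")
        self._w_normal = (system.plane.total_mass * system.plane.gravity
                          * np.cos(system.slope_angle))

    def feedforward_torques(self, t: float) -> np.ndarray:
        """Quasi-static holding torques at the desired posture.

        Inverse dynamics of the desired configuration at rest, with the
        slope-normal component of gravity distributed over the ski contact
        points such that the center of pressure lies under the whole-body
        COM (static balance); the remaining tangential gravity component is
        what makes the skier glide and needs no actuation.
        """
        sysm = self.system
        q_des = np.asarray(self.q_des_fn(t), dtype=float)
        loads = support_loads(sysm, q_des, self._w_normal,
                              tangential_accel=self.tangential_accel)
        Q = sysm.plane.inverse_dynamics(q_des, np.zeros_like(q_des), np.zeros_like(q_des),
                                        loads=loads)
        Q[:3] = 0.0     # pelvis rows are not actuated
        return Q

    def _com_error(self, t: float, q: np.ndarray, qd: np.ndarray):
        """Tangential offset (and rate) of the balance COM relative to its
        planned position over the contact points."""
        sysm = self.system
        t_hat = sysm._t_hat
        kin = sysm.plane.kinematics(q, qd)
        com = balance_com(sysm, kin, self.tangential_accel)
        states = [sysm.plane.point_state(kin, b, o) for b, o, _ in sysm.contact_points]
        mid = sum(np.asarray(p) for p, _, _ in states) / len(states)
        mid_v = sum(np.asarray(v) for _, v, _ in states) / len(states)
        m_tot = sysm.plane.total_mass
        com_v = sum(b.mass * np.asarray(sysm.plane.point_state(kin, b.name, b.com_offset)[1])
                    for b in sysm.plane.bodies) / m_tot
        q_des = np.asarray(self.q_des_fn(t), dtype=float)
        kin_d = sysm.plane.kinematics(q_des)
        com_d = balance_com(sysm, kin_d, self.tangential_accel)
        mid_d = sum(np.asarray(sysm.plane.point_state(kin_d, b, o)[0])
                    for b, o, _ in sysm.contact_points) / len(states)
        err = float((com - mid) @ t_hat) - float((com_d - mid_d) @ t_hat)
        rate = float((com_v - mid_v) @ t_hat)
        return err, rate

    def desired_torques(self, t: float, q: np.ndarray, qd: np.ndarray,
                        com_err: float = 0.0, com_rate: float = 0.0) -> np.ndarray:
        q_des = np.array(self.q_des_fn(t), dtype=float)
        qd_des = np.array(self.qd_des_fn(t), dtype=float)
        pitch_err = q[self.pitch_idx] - q_des[self.pitch_idx]
        pitch_rate = qd[self.pitch_idx] - qd_des[self.pitch_idx]
        # COM ahead of plan -> move the CoP forward: plantarflex (negative bias)
        com_term = self.gains.com_gain * com_err + self.gains.com_rate_gain * com_rate
        bias = (self.gains.balance_gain * pitch_err
                + self.gains.balance_rate_gain * pitch_rate - com_term)
        for j in self.ankle_idx:
            q_des[j] = q_des[j] + bias
        hip_bias = (self.gains.hip_balance_gain * pitch_err
                    + self.gains.hip_balance_rate_gain * pitch_rate - 0.5 * com_term)
        for j in self.hip_idx:
            q_des[j] = q_des[j] + hip_bias
        return (self.feedforward_torques(t)
                + self.kp * (q_des - q) + self.kd * (qd_des - qd))

    def excitations(self, t: float, x: np.ndarray) -> np.ndarray:
        """Stateful torque-tracking law.

        The static redundancy map is only a rough calibration (rigid tendon,
        no passive forces), so the controller additionally integrates the gap
        between the demanded joint torques and the torques the muscles are
        actually producing, distributing the correction least-norm over the
        capacity matrix.  This keeps posture control robust to Hill-model
        nonlinearities without needing an inverse muscle model.
        """
        sysm = self.system
        q, qd, s, a, _ = sysm.split(x)
        com_err, com_rate = self._com_error(t, q, qd)
        tau_dem = self.desired_torques(t, q, qd, com_err, com_rate)[self.joint_idx]
        tau_mus, _, _ = sysm.muscle_torques(q, s, np.zeros_like(s), a)
        tau_err = tau_dem - tau_mus[self.joint_idx]
        _, arms = sysm.muscles.lengths_and_arms(q)
        f_unit = sysm.muscles.unit_force_estimate(q)
        A = (arms[..., self.joint_idx] * f_unit[:, None]).T
        G = A @ A.T + 1e-6 * np.trace(A @ A.T) * np.eye(A.shape[0])
        du = A.T @ np.linalg.solve(G, tau_err)
        if self._u is None:
            self._u = redundancy_excitations(sysm, q, tau_dem, self.joint_idx,
                                             bias=self.gains.cocontraction)
        # leak: torque-productive activity is restored by the correction term
        # each step, antagonist co-contraction (torque-neutral) decays away
        self._u = np.clip(self.leak * self._u + self.integral_rate * du, 0.0, 1.0)
        return np.clip(self._u + self.gains.cocontraction, 0.0, 1.0)

    def reset(self):
        self._u = None

    __call__ = excitations


def least_effort_distribution(A: np.ndarray, tau: np.ndarray,
                              exponent: float = 2.0, iters: int = 80) -> np.ndarray:
    """min sum(u^p) s.t. A u = tau, u >= 0 (capacity matrix A >= 0 columns).

    Exponent 2 is the least-norm solution on the sign-rectified capacities;
    higher exponents are solved by iteratively reweighted least-norm: the
    stationarity condition ``p u^(p-1) = A^T lambda`` is matched by weighted
    least squares with ``W = u^(2-p)``, which spreads the load more evenly
    over synergists (fatigue-like criterion).
    """
    A = np.asarray(A, dtype=float)
    tau = np.asarray(tau, dtype=float)
    W = np.ones(A.shape[1])
    u = np.zeros(A.shape[1])
    n_it = 1 if exponent == 2.0 else iters
    gamma = 0.3    # damped reweighting: undamped IRLS oscillates for p > 2
    for _ in range(n_it):
        AW = A * W
        G = AW @ A.T + 1e-10 * np.trace(AW @ A.T) * np.eye(A.shape[0])
        lam = np.linalg.solve(G, tau)
        u = np.clip(W * (A.T @ lam), 0.0, 1.0)
        if exponent != 2.0:
            target = np.maximum(u, 1e-4) ** (2.0 - exponent)
            W = W ** (1.0 - gamma) * target ** gamma
            W = W / W.max()
    return u


def redundancy_excitations(system, q, tau_des, joint_idx, bias: float = 0.02,
                           exponent: float = 2.0) -> np.ndarray:
    """Distribute desired joint torques over muscles; least effort, bounds [0,1].

    The capacity matrix is ``A[j, m] = arm(q) * f_unit(q)`` with the
    rigid-tendon isometric force estimate; a small co-contraction bias keeps
    every muscle minimally excited.
    """
    mus = system.muscles
    _, arms = mus.lengths_and_arms(np.asarray(q, dtype=float))
    f_unit = mus.unit_force_estimate(q)
    A = (arms[..., joint_idx] * f_unit[:, None]).T         # (n_j, n_m)
    u = least_effort_distribution(A, np.asarray(tau_des, dtype=float),
                                  exponent=exponent)
    return np.clip(u + bias, 0.0, 1.0)


def static_redundancy_activations(system, q, tau_des, joint_idx,
                                  exponent: float = 2.0) -> np.ndarray:
    """Per-node static muscle-redundancy solve: min sum(a^p) s.t. torque match.

    Uses the isometric force capacity at the given posture (rigid-tendon
    approximation) with box bounds [0, 1]; solved as a bounded least-squares
    problem with a strong torque-match penalty.
    """
    from scipy.optimize import lsq_linear

    mus = system.muscles
    l_mt, arms = mus.lengths_and_arms(np.asarray(q, dtype=float))
    s_iso = system.muscle_equilibrium_s(q, np.zeros(system.n_m))
    res0, f_pass = mus.contraction_residuals(s_iso, np.zeros_like(s_iso),
                                             np.zeros(system.n_m), l_mt)
    res1, f_full = mus.contraction_residuals(s_iso, np.zeros_like(s_iso),
                                             np.ones(system.n_m), l_mt)
    cap = np.maximum(f_full - f_pass, 1.0)                 # N per unit activation
    A = (arms[..., joint_idx] * cap[:, None]).T
    tau = np.asarray(tau_des, dtype=float) - (arms[..., joint_idx].T @ f_pass)
    penalty = 1e4
    n_m = A.shape[1]
    M = np.vstack([penalty * A, np.eye(n_m)])
    b = np.concatenate([penalty * tau, np.zeros(n_m)])
    sol = lsq_linear(M, b, bounds=(0.0, 1.0), max_iter=200)
    return sol.x
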