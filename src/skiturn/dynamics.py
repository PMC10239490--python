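"""Implicit system dynamics of the muscle-driven planar skier.

The state is ``x = [q, qdot, s, a, mem]``: generalized coordinates and
velocities, projected fiber lengths, activations, and the hypoplastic
contact-memory depth per ski contact point.  Controls are the neural
excitations ``u``.  The whole system is one residual ``f(x, xdot, u) = 0``
stacking

1. velocity consistency          (d/dt of q  == qdot states),
2. multibody dynamics            (inverse dynamics == muscle + boot torques),
3. muscle contraction residuals  (tendon-fiber force balance),
4. muscle activation residuals   (first-order excitation lag),
5. contact-memory dynamics       (memory relaxes up toward the current depth).

Rows are scaled to O(1) so the same residual serves the per-step root solver
and the collocation NLP without further conditioning.  Every operation is
batched over a leading axis and complex-step differentiable.

The snow is an inclined plane dropping in +x; gravity is vertical in the
world frame (x downhill-horizontal, z up).  Contact forces (hypoplastic
normal force + regularized Coulomb friction) act at named ski points; air
drag acts at the pelvis COM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._smooth import smooth_pos, softplus
from .body import BootParams, boot_moment, build_skier_model
from .config import load_model_config
from .muscles import MuscleGroup, load_muscles
from .planar import PlanarModel, planar_from_config
from .ski_snow import AeroParams, SnowSurface, hypoplastic_normal_force

MEMORY_RATE = 50.0     # 1/s, relaxation of the contact memory toward the depth


class IntegrationError(RuntimeError):
    def __init__(self, step: int, message: str):
        super().__init__(f"integration failed at step {step}: {message}")
        self.step = step


@dataclass
class Trajectory:
    """Time series of states/controls on a uniform mesh."""

    times: np.ndarray          # (N,)
    states: np.ndarray         # (N, n_x)
    controls: np.ndarray       # (N, n_u); row k is the control over (t_{k-1}, t_k]

    @property
    def h(self) -> float:
        return float(self.times[1] - self.times[0])


class SkierSystem:
    """Planar skier + muscles + ski-snow contact bundled into one residual."""

    def __init__(self, config: str | dict = "reduced_planar"):
        cfg = load_model_config(config) if isinstance(config, str) else config
        self.config = cfg
        self.model3d = build_skier_model(cfg)
        self.plane: PlanarModel = planar_from_config(self.model3d)
        self.muscles = MuscleGroup(load_muscles(cfg["muscle_table"]), self.plane.coordinate_names)
        self.boot = BootParams.from_config(cfg.get("boot", {}))
        self.snow = SnowSurface.from_config(cfg.get("snow", {}))
        aero = cfg.get("aero", {})
        self.aero = AeroParams(cda=aero.get("cda", 0.3), rho=aero.get("rho", 1.07),
                               wind=np.asarray(aero.get("wind", [0.0, 0.0, 0.0]))[:3])
        fr = cfg.get("friction", {})
        self.mu = fr.get("mu", 0.08)
        self.slip_eps = fr.get("slip_epsilon", 1e-3)
        # passive viscous damping of joint tissues, N*m*s/rad
        self.joint_damping = cfg.get("joint_damping", 1.0)
        # contact smoothing half-width (m): sets the linearization radius the
        # gradient-based NLP sees around contact onset
        self.contact_blend = cfg.get("snow", {}).get("contact_blend", 2e-3)
        # soft knee hyperextension stop (ligamentous): quadratic torque beyond
        # knee angle > stop angle (knee coordinate is negative in flexion)
        self.knee_stop_angle = np.deg2rad(cfg.get("knee_stop_angle_deg", -6.0))
        self.knee_stop_stiffness = cfg.get("knee_stop_stiffness", 2000.0)
        beta = np.deg2rad(cfg.get("snow", {}).get("slope_angle_deg", 12.3))
        self.slope_angle = beta
        self._n_hat = np.array([np.sin(beta), np.cos(beta)])   # in-plane surface normal
        self._t_hat = np.array([np.cos(beta), -np.sin(beta)])  # downhill tangent
        # contact points in model order
        self.contact_points = []
        for b in self.plane.bodies:
            for name, off in b.points.items():
                self.contact_points.append((b.name, off, name))
        if not self.contact_points:
            raise ValueError("model config declares no planar contact points")
        self.n_q = self.plane.ndof
        self.n_m = len(self.muscles.specs)
        self.n_c = len(self.contact_points)
        self.ankle_coords = [i for i, n in enumerate(self.plane.coordinate_names) if "ankle" in n]
        # row scales: translations ~ body weight, rotations ~ 200 N*m
        w = self.plane.total_mass * self.plane.gravity
        self._dyn_scale = np.where(
            [("_x" in n or "_z" in n) and n.startswith("pelvis") for n in self.plane.coordinate_names],
            w, 200.0)
        self._act_scale = 0.05     # s: activation residual (1/s) -> O(1)
        self._mem_scale = 1.0      # memory residual already m/s * small rates

    # -- layout -------------------------------------------------------------

    @property
    def n_x(self) -> int:
        return 2 * self.n_q + 2 * self.n_m + self.n_c

    @property
    def n_u(self) -> int:
        return self.n_m

    def split(self, x):
        q = x[..., :self.n_q]
        qd = x[..., self.n_q:2 * self.n_q]
        s = x[..., 2 * self.n_q:2 * self.n_q + self.n_m]
        a = x[..., 2 * self.n_q + self.n_m:2 * self.n_q + 2 * self.n_m]
        mem = x[..., 2 * self.n_q + 2 * self.n_m:]
        return q, qd, s, a, mem

    def pack(self, q, qd, s, a, mem=None):
        if mem is None:
            mem = np.zeros(np.shape(q)[:-1] + (self.n_c,))
        return np.concatenate([q, qd, s, a, mem], axis=-1)

    def state_labels(self) -> list[str]:
        names = self.plane.coordinate_names
        return (names + [f"{n}_dot" for n in names]
                + [f"s_{m}" for m in self.muscles.names]
                + [f"a_{m}" for m in self.muscles.names]
                + [f"mem_{cp[2]}" for cp in self.contact_points])

    # -- environment forces ---------------------------------------------------

    def contact_terms(self, kin, qdim, mem):
        """Per-contact-point (depth, rate, normal force, in-plane force, world point).

        Depth is the distance below the inclined snow plane along its normal.
        """
        depths, rates, normals, loads = [], [], [], []
        for i, (body, off, _) in enumerate(self.contact_points):
            p, v, _ = self.plane.point_state(kin, body, off)
            gap = p[..., 0] * self._n_hat[0] + p[..., 1] * self._n_hat[1]
            # softplus clamp: smooth over ~contact_blend near the surface but
            # with an exponential tail, so airborne forces vanish identically
            depth = softplus(-gap, sharpness=1.0 / self.contact_blend)
            rate = -(v[..., 0] * self._n_hat[0] + v[..., 1] * self._n_hat[1])
            f_n = hypoplastic_normal_force(depth, rate, mem[..., i], self.snow.k_load,
                                           self.snow.stiffness_ratio, self.snow.rate_damping)
            v_t = v[..., 0] * self._t_hat[0] + v[..., 1] * self._t_hat[1]
            sat = v_t / np.sqrt(v_t * v_t + self.slip_eps**2)
            f_t = -self.mu * f_n * sat
            force = f_n[..., None] * self._n_hat + f_t[..., None] * self._t_hat
            depths.append(depth)
            rates.append(rate)
            normals.append(f_n)
            loads.append((body, off, force, None))
        return depths, rates, normals, loads

    def drag_load(self, kin):
        pelvis = self.plane.bodies[0]
        _, v, _ = self.plane.point_state(kin, pelvis.name, pelvis.com_offset)
        wind2 = np.array([self.aero.wind[0], self.aero.wind[2]])
        v_rel = v - wind2
        speed = np.sqrt(np.sum(v_rel * v_rel, axis=-1, keepdims=True) + 1e-12)
        force = -0.5 * self.aero.rho * self.aero.cda * speed * v_rel
        return (pelvis.name, pelvis.com_offset, force, None)

    def muscle_torques(self, q, s, sdot, a):
        """(generalized muscle torques, tendon forces, contraction residuals)."""
        l_mt, arms = self.muscles.lengths_and_arms(q)
        res_c, f_t = self.muscles.contraction_residuals(s, sdot, a, l_mt)
        tau = np.einsum("...mj,...m->...j", arms, f_t)
        return tau, f_t, res_c

    # -- the implicit residual ------------------------------------------------

    def residual(self, x, xdot, u):
        """Scaled implicit residual f(x, xdot, u); zero on consistent motion."""
        x = np.asarray(x)
        xdot = np.asarray(xdot)
        u = np.asarray(u)
        batch = np.broadcast_shapes(x.shape[:-1], xdot.shape[:-1], u.shape[:-1])
        x = np.broadcast_to(x, batch + x.shape[-1:])
        xdot = np.broadcast_to(xdot, batch + xdot.shape[-1:])
        u = np.broadcast_to(u, batch + u.shape[-1:])
        q, qd, s, a, mem = self.split(x)
        qdot_x, qdd, sdot, adot, memdot = self.split(xdot)

        rows_vel = qdot_x - qd

        kin = self.plane.kinematics(q, qd, qdd)
        depths, rates, f_ns, loads = self.contact_terms(kin, q, mem)
        loads = loads + [self.drag_load(kin)]
        Q_needed = self.plane.inverse_dynamics(q, qd, qdd, loads=loads)
        tau_mus, f_t, res_contraction = self.muscle_torques(q, s, sdot, a)
        tau = tau_mus + self._passive_torques(q, qd)
        rows_dyn = (Q_needed - tau) / self._dyn_scale

        rows_act = self.muscles.activation_residuals(a, adot, u) * self._act_scale

        depth_arr = np.stack(depths, axis=-1)
        rows_mem = (memdot - MEMORY_RATE * smooth_pos(depth_arr - mem, 1e-3)) * self._mem_scale

        return np.concatenate([rows_vel, rows_dyn, res_contraction, rows_act, rows_mem], axis=-1)

    def system_residual(self, x, xdot, u):
        """Public alias with dimension checks."""
        x, xdot, u = np.asarray(x), np.asarray(xdot), np.asarray(u)
        if x.shape[-1] != self.n_x or xdot.shape[-1] != self.n_x or u.shape[-1] != self.n_u:
            raise ValueError(
                f"dimension mismatch: expected n_x={self.n_x}, n_u={self.n_u}, "
                f"got {x.shape[-1]}, {xdot.shape[-1]}, {u.shape[-1]}")
        if not (np.all(np.isfinite(np.real(x))) and np.all(np.isfinite(np.real(xdot)))
                and np.all(np.isfinite(np.real(u)))):
            raise FloatingPointError("non-finite state/control input")
        return self.residual(x, xdot, u)

    # -- forward simulation ---------------------------------------------------

    def defect(self, x_prev, x_next, u_next, h, theta: float = 1.0):
        """One-step theta-method defect; theta=1 is the implicit Euler formula."""
        xdot = (x_next - x_prev) / h
        x_eval = theta * x_next + (1.0 - theta) * x_prev
        return self.residual(x_eval, xdot, u_next)

    def step(self, x_prev, u_next, h, theta: float = 1.0, tol: float = 1e-10):
        def fun(z):
            return np.real(self.defect(x_prev, z, u_next, h, theta))

        def jac(z):
            n = z.size
            J = np.empty((n, n))
            for j in range(n):
                zp = z.astype(complex)
                zp[j] += 1e-30j
                J[:, j] = np.imag(self.defect(x_prev, zp, u_next, h, theta)) / 1e-30
            return J

        sol = optimize.root(fun, x_prev, jac=jac, method="hybr", tol=tol)
        return sol

    def forward_simulate(self, x0, u_of_t, T: float, dt: float, theta: float = 1.0,
                         controller=None, tol: float = 1e-10) -> Trajectory:
        """Integrate the implicit residual with a per-step root solve.

        ``u_of_t(t)`` gives the open-loop excitation at the step endpoint;
        alternatively ``controller(t, x)`` computes it from the current state
        (the value actually applied is recorded, so the returned trajectory is
        exactly consistent with its stored controls).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        n_steps = int(round(T / dt))
        times = np.arange(n_steps + 1) * dt
        X = np.empty((n_steps + 1, self.n_x))
        U = np.empty((n_steps + 1, self.n_u))
        X[0] = x0
        U[0] = np.clip(controller(0.0, x0) if controller else u_of_t(0.0), 0.0, 1.0)
        for k in range(n_steps):
            t_next = times[k + 1]
            u = controller(times[k], X[k]) if controller else u_of_t(t_next)
            u = np.clip(u, 0.0, 1.0)
            sol = self.step(X[k], u, dt, theta=theta, tol=tol)
            res_norm = np.max(np.abs(sol.fun))
            if not sol.success and res_norm > 1e-6:
                raise IntegrationError(k, sol.message)
            X[k + 1] = sol.x
            U[k + 1] = u
        return Trajectory(times=times, states=X, controls=U)

    # -- initial states -------------------------------------------------------

    def muscle_equilibrium_s(self, q, a=None):
        """Projected fiber lengths solving the isometric contraction residual."""
        q = np.asarray(q, dtype=float)
        a = np.zeros(self.n_m) if a is None else np.asarray(a)
        l_mt, _ = self.muscles.lengths_and_arms(q)

        def fun(s):
            r, _ = self.muscles.contraction_residuals(s, np.zeros_like(s), a, l_mt)
            return r

        # rigid-tendon start: fiber takes up everything beyond the slack length
        s0 = np.clip(l_mt - self.muscles.l_slack * 1.01,
                     0.35 * self.muscles.s_opt, 1.65 * self.muscles.s_opt)
        sol = optimize.root(fun, s0, method="hybr", tol=1e-12)
        if np.max(np.abs(sol.fun)) > 1e-8:
            raise RuntimeError("muscle fiber equilibrium solve failed")
        return sol.x

    def initial_state(self, q, qd=None, a=None):
        """Assembled state at given coordinates with isometric muscle states."""
        q = np.asarray(q, dtype=float)
        qd = np.zeros(self.n_q) if qd is None else np.asarray(qd)
        a = np.full(self.n_m, 0.02) if a is None else np.asarray(a)
        s = self.muscle_equilibrium_s(q, a)
        kin = self.plane.kinematics(q)
        mem = np.zeros(self.n_c)
        for i, (body, off, _) in enumerate(self.contact_points):
            p, _, _ = self.plane.point_state(kin, body, off)
            gap = p[0] * self._n_hat[0] + p[1] * self._n_hat[1]
            mem[i] = max(-gap, 0.0)
        return self.pack(q, qd, s, a, mem)

    # -- energetics -----------------------------------------------------------

    def mechanical_energy(self, x):
        """Kinetic + gravitational potential energy of the rigid bodies."""
        q, qd, _, _, _ = self.split(np.asarray(x))
        kin = self.plane.kinematics(q, qd)
        E = 0.0
        for i, b in enumerate(self.plane.bodies):
            pc, vc, _ = self.plane.point_state(kin, b.name, b.com_offset)
            E = E + 0.5 * b.mass * np.sum(vc * vc, axis=-1) + 0.5 * b.inertia * kin["om"][i] ** 2
            E = E + b.mass * self.plane.gravity * pc[..., 1]
        return E

    def _passive_torques(self, q, qd):
        """Boot moments at the ankles, knee hyperextension stops, and viscous
        joint-tissue damping."""
        tau = np.zeros(np.broadcast_shapes(q.shape, qd.shape), dtype=np.result_type(q, qd))
        tau[..., 3:] = -self.joint_damping * qd[..., 3:]
        for j in self.ankle_coords:
            tau[..., j] = tau[..., j] + boot_moment(q[..., j], qd[..., j], self.boot)
        for j, n in enumerate(self.plane.coordinate_names):
            if "knee" in n:
                over = smooth_pos(q[..., j] - self.knee_stop_angle, 1e-3)
                tau[..., j] = tau[..., j] - self.knee_stop_stiffness * over * over
        return tau

    def applied_power(self, x, xdot):
        """Power of actuation (muscles + boot + tissue damping, on the joints)
        and of environment forces (contact + drag, on the bodies)."""
        q, qd, s, a, mem = self.split(np.asarray(x))
        _, _, sdot, _, _ = self.split(np.asarray(xdot))
        kin = self.plane.kinematics(q, qd)
        _, _, _, loads = self.contact_terms(kin, q, mem)
        loads = loads + [self.drag_load(kin)]
        P_env = 0.0
        for body, off, force, _ in loads:
            _, v, _ = self.plane.point_state(kin, body, off)
            P_env = P_env + np.sum(force * v, axis=-1)
        tau_mus, _, _ = self.muscle_torques(q, s, sdot, a)
        tau = tau_mus + self._passive_torques(q, qd)
        P_act = np.sum(tau * qd, axis=-1)
        return P_act, P_env
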