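"""Direct-collocation tracking optimal control.

The continuous problem — find excitations u(t) such that the muscle-driven
skier reproduces reference kinematics — is transcribed on a uniform mesh with
the implicit Euler formula: decision variables are the states and controls at
every node, and the dynamics enter as per-interval defect constraints

    defect_k = f(x_{k+1}, (x_{k+1} - x_k)/h, u_{k+1}) = 0 .

The objective is a weighted sum of three parts (tracking error, muscle
effort, regularization of state/control derivatives), normalized per channel,
muscle and variable and averaged over the horizon:

    J = (1/T) * integral[ (w1/n_d)||err_d||^2 + (w2/n_m)||a||_p^p
                          + (w3/n_xu)(||xdot||^2 + ||udot||^2) ] dt

with the rectangle rule on the implicit-Euler nodes.

Solver: every objective part is a sum of squares (for effort exponent p the
integrand a^p is the square of a^(p/2) on a >= 0), so the NLP is solved as a
bound-constrained nonlinear least-squares problem with the defects handled by
an augmented-Lagrangian outer loop: minimize ||r_obj||^2 + rho*||c +
lambda/rho||^2 with a scaled Levenberg-Marquardt method whose steps come from
a sparse direct factorization of the damped normal equations; multipliers are
updated and rho increased until the defects meet the feasibility tolerance.
Defect Jacobians are exact (complex step, vectorized over the mesh);
objective Jacobians are analytic.  The method is local: on this nonconvex
contact-rich landscape different initial guesses can converge to different
locally optimal trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .control import ExcitationPD
from .dynamics import SkierSystem, Trajectory

log = logging.getLogger(__name__)

_CS = 1e-30          # complex-step size


class SolverError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class ObjectiveSpec:
    w1: float = 1.0
    w2: float = 10.0
    w3: float = 1e-3
    effort_exponent: float = 2.0
    angle_scale: float = np.deg2rad(10.0)    # err_d normalization for angles
    translation_scale: float = 0.1           # m, for pelvis translations

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("objective weights must be nonnegative")
        if self.effort_exponent < 2:
            raise ValueError("effort exponent must be >= 2")


@dataclass
class CollocationGrid:
    n_mesh: int = 75
    T: float = 2.0

    def __post_init__(self):
        if self.n_mesh < 2:
            raise ValueError("need at least 2 mesh points")
        if self.T <= 0:
            raise ValueError("horizon must be positive")

    @property
    def h(self) -> float:
        return self.T / (self.n_mesh - 1)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.n_mesh)


@dataclass
class ReferenceData:
    """Tracked channels on the mesh: a table with 'time' plus coordinate columns."""

    channels: pd.DataFrame
    tracked: list[str]

    def __post_init__(self):
        missing = [c for c in self.tracked if c not in self.channels.columns]
        if missing:
            raise ValueError(f"reference missing tracked channels: {missing}")

    def resampled(self, times: np.ndarray) -> np.ndarray:
        """(len(times), n_tracked) array, linearly interpolated."""
        t = self.channels["time"].to_numpy()
        return np.stack([np.interp(times, t, self.channels[c].to_numpy())
                         for c in self.tracked], axis=1)

    @classmethod
    def from_fixture(cls, fixture, system: SkierSystem) -> "ReferenceData":
        """Tracked set = pelvis translations + configured angle channels."""
        angles = system.config.get("planar", {}).get(
            "tracked_angle_channels",
            [n for n in system.plane.coordinate_names if n not in ("pelvis_x", "pelvis_z")])
        return cls(channels=fixture.channels, tracked=["pelvis_x", "pelvis_z"] + list(angles))


@dataclass
class NLPSolution:
    states: np.ndarray
    controls: np.ndarray
    times: np.ndarray
    objective: float
    tracking_part: float
    effort_part: float
    regularization_part: float
    constraint_violation: float
    status: str
    outer_iterations: int

    @property
    def success(self) -> bool:
        return self.status == "converged"

    def trajectory(self) -> Trajectory:
        return Trajectory(times=self.times, states=self.states, controls=self.controls)


def discretize_dynamics(system: SkierSystem, grid: CollocationGrid):
    """Per-interval implicit-Euler defect function on stacked node arrays."""

    def defects(X, U):
        return system.defect(X[:-1], X[1:], U[1:], grid.h)

    return defects


def objective_terms(problem: "TrackingProblem", X, U):
    """(J, tracking part, effort part, regularization part) on the grid.

    The integral uses the rectangle rule on the right endpoints (matching the
    implicit-Euler nodes); parts are reported weighted, so they sum to J.
    """
    return problem.objective_parts(problem.pack_z(X, U))


class TrackingProblem:
    """Assembled NLP: decision vector z = [X.ravel(), U.ravel()]."""

    def __init__(self, system: SkierSystem, ref: ReferenceData,
                 spec: ObjectiveSpec | None = None,
                 grid: CollocationGrid | None = None,
                 bounds: dict | None = None):
        self.system = system
        self.spec = spec or ObjectiveSpec()
        self.grid = grid or CollocationGrid()
        self.ref = ref
        names = system.plane.coordinate_names
        self.tracked_idx = np.array([names.index(c) for c in ref.tracked])
        self.scales = np.array([self.spec.translation_scale if c in ("pelvis_x", "pelvis_z")
                                else self.spec.angle_scale for c in ref.tracked])
        self.ref_values = ref.resampled(self.grid.times)
        self.N = self.grid.n_mesh
        self.n_x, self.n_u = system.n_x, system.n_u
        self.n_z = self.N * self.n_x + self.N * self.n_u
        self.lb, self.ub = self._variable_bounds(bounds or system.config.get("bounds", {}))
        if np.any(self.lb >= self.ub):
            raise ValueError("infeasible bounds: lower >= upper")
        self._build_sparsity()

    # -- layout --------------------------------------------------------------

    def split_z(self, z):
        X = z[:self.N * self.n_x].reshape(self.N, self.n_x)
        U = z[self.N * self.n_x:].reshape(self.N, self.n_u)
        return X, U

    def pack_z(self, X, U):
        return np.concatenate([np.asarray(X).ravel(), np.asarray(U).ravel()])

    def _variable_bounds(self, b):
        sysm = self.system
        names = sysm.plane.coordinate_names
        q_lb, q_ub = np.empty(sysm.n_q), np.empty(sysm.n_q)
        for j, n in enumerate(names):
            if n == "pelvis_x":
                lo, hi = b.get("pelvis_x", [-50, 100])
            elif n == "pelvis_z":
                lo, hi = b.get("pelvis_z", [-30, 30])
            elif "pitch" in n:
                lo, hi = np.deg2rad(b.get("pelvis_pitch_deg", [-80, 80]))
            elif "hip" in n:
                lo, hi = np.deg2rad(b.get("hip_deg", [-60, 130]))
            elif "knee" in n:
                lo, hi = np.deg2rad(b.get("knee_deg", [-150, 5]))
            else:
                lo, hi = np.deg2rad(b.get("ankle_deg", [-40, 45]))
            q_lb[j], q_ub[j] = lo, hi
        qd_lim = np.where(["pelvis_x" == n or "pelvis_z" == n for n in names],
                          b.get("translation_rate", [-40, 40])[1],
                          np.deg2rad(b.get("joint_rate_deg_s", [-1000, 1000])[1]))
        s_rel = b.get("fiber_length_rel", [0.3, 1.7])
        s_lb = s_rel[0] * sysm.muscles.s_opt
        s_ub = s_rel[1] * sysm.muscles.s_opt
        a_lb, a_ub = b.get("activation", [0.0, 1.0])
        m_lb, m_ub = b.get("memory_depth", [0.0, 0.5])
        x_lb = np.concatenate([q_lb, -qd_lim, s_lb, np.full(sysm.n_m, a_lb),
                               np.full(sysm.n_c, m_lb)])
        x_ub = np.concatenate([q_ub, qd_lim, s_ub, np.full(sysm.n_m, a_ub),
                               np.full(sysm.n_c, m_ub)])
        u_lb, u_ub = b.get("excitation", [0.0, 1.0])
        lb = np.concatenate([np.tile(x_lb, self.N), np.full(self.N * self.n_u, u_lb)])
        ub = np.concatenate([np.tile(x_ub, self.N), np.full(self.N * self.n_u, u_ub)])
        return lb, ub

    # -- objective residuals (sum of squares == J) ----------------------------

    def _obj_weights(self):
        h, T = self.grid.h, self.grid.T
        spec = self.spec
        n_d = len(self.tracked_idx)
        n_xu = self.n_x + self.n_u
        w_track = np.sqrt(spec.w1 * h / (T * n_d)) / self.scales
        w_eff = np.sqrt(spec.w2 * h / (T * self.n_u))
        w_reg = np.sqrt(spec.w3 * h / (T * n_xu))
        return w_track, w_eff, w_reg

    def objective_residuals(self, z):
        X, U = self.split_z(z)
        w_track, w_eff, w_reg = self._obj_weights()
        h = self.grid.h
        p = self.spec.effort_exponent
        a = X[1:, 2 * self.system.n_q + self.system.n_m:
              2 * self.system.n_q + 2 * self.system.n_m]
        r_track = ((X[1:, self.tracked_idx] - self.ref_values[1:]) * w_track).ravel()
        r_eff = (w_eff * np.maximum(a, 0.0) ** (p / 2.0)).ravel()
        r_regx = (w_reg * (X[1:] - X[:-1]) / h).ravel()
        r_regu = (w_reg * (U[1:] - U[:-1]) / h).ravel()
        return np.concatenate([r_track, r_eff, r_regx, r_regu])

    def objective_parts(self, z):
        """(J, tracking, effort, regularization); parts sum exactly to J."""
        X, U = self.split_z(z)
        n1 = (self.N - 1) * len(self.tracked_idx)
        n2 = (self.N - 1) * self.n_u
        r = self.objective_residuals(z)
        tr = float(np.sum(r[:n1] ** 2))
        ef = float(np.sum(r[n1:n1 + n2] ** 2))
        rg = float(np.sum(r[n1 + n2:] ** 2))
        return tr + ef + rg, tr, ef, rg

    # -- defects ---------------------------------------------------------------

    def defects(self, z):
        X, U = self.split_z(z)
        return self.system.defect(X[:-1], X[1:], U[1:], self.grid.h).ravel()

    def defect_jacobian_blocks(self, z):
        """(J_prev, J_next, J_u): (K, n_x, n_x|n_u) exact derivative blocks."""
        X, U = self.split_z(z)
        K = self.N - 1
        h = self.grid.h
        xp = X[:-1].astype(complex)
        xn = X[1:].astype(complex)
        uu = U[1:].astype(complex)
        sysm = self.system

        def block(which, n_cols):
            # stack the column perturbations along a leading axis and evaluate
            # the defect for all intervals at once
            if which == "prev":
                arr = np.broadcast_to(xp, (n_cols,) + xp.shape).copy()
                idx = np.arange(n_cols)
                arr[idx, :, idx] += 1j * _CS
                out = sysm.defect(arr, xn, uu, h)
            elif which == "next":
                arr = np.broadcast_to(xn, (n_cols,) + xn.shape).copy()
                idx = np.arange(n_cols)
                arr[idx, :, idx] += 1j * _CS
                out = sysm.defect(xp, arr, uu, h)
            else:
                arr = np.broadcast_to(uu, (n_cols,) + uu.shape).copy()
                idx = np.arange(n_cols)
                arr[idx, :, idx] += 1j * _CS
                out = sysm.defect(xp, xn, arr, h)
            return np.moveaxis(np.imag(out) / _CS, 0, 2)   # (K, n_res, n_cols)

        return block("prev", self.n_x), block("next", self.n_x), block("u", self.n_u)

    # -- sparse jacobians -------------------------------------------------------

    def _build_sparsity(self):
        N, n_x, n_u = self.N, self.n_x, self.n_u
        K = N - 1
        n_d = len(self.tracked_idx)
        rows, cols = [], []
        r0 = 0
        # tracking rows: node k (1..N-1), tracked coord c
        for k in range(1, N):
            for c in self.tracked_idx:
                rows.append(r0)
                cols.append(k * n_x + c)
                r0 += 1
        # effort rows
        a0 = 2 * self.system.n_q + self.system.n_m
        for k in range(1, N):
            for m in range(n_u):
                rows.append(r0)
                cols.append(k * n_x + a0 + m)
                r0 += 1
        # state regularization rows: (x_{k+1} - x_k)/h
        for k in range(K):
            for i in range(n_x):
                rows += [r0, r0]
                cols += [k * n_x + i, (k + 1) * n_x + i]
                r0 += 1
        # control regularization rows
        u_off = N * n_x
        for k in range(K):
            for i in range(n_u):
                rows += [r0, r0]
                cols += [u_off + k * n_u + i, u_off + (k + 1) * n_u + i]
                r0 += 1
        self._n_obj_rows = r0
        # defect rows: K blocks, each n_x rows, dense over [x_k, x_{k+1}, u_{k+1}]
        for k in range(K):
            for i in range(n_x):
                for j in range(n_x):
                    rows += [r0, r0]
                    cols += [k * n_x + j, (k + 1) * n_x + j]
                for j in range(n_u):
                    rows.append(r0)
                    cols.append(u_off + (k + 1) * n_u + j)
                r0 += 1
        self._jac_rows = np.array(rows)
        self._jac_cols = np.array(cols)
        self._n_rows_total = r0

    def _objective_jac_data(self, z):
        X, U = self.split_z(z)
        w_track, w_eff, w_reg = self._obj_weights()
        h = self.grid.h
        p = self.spec.effort_exponent
        N, n_x, n_u = self.N, self.n_x, self.n_u
        K = N - 1
        data = []
        data.append(np.tile(w_track, K))                       # tracking
        a = X[1:, 2 * self.system.n_q + self.system.n_m:
              2 * self.system.n_q + 2 * self.system.n_m]
        data.append((w_eff * (p / 2.0) * np.maximum(a, 1e-12) ** (p / 2.0 - 1.0)).ravel())
        wr = w_reg / h
        data.append(np.tile([-wr, wr], K * n_x))
        data.append(np.tile([-wr, wr], K * n_u))
        return np.concatenate(data)

    def full_jacobian(self, z, defect_weight: float = 1.0):
        """Sparse Jacobian of [objective residuals; defect_weight * defects]."""
        J_prev, J_next, J_u = self.defect_jacobian_blocks(z)
        # per defect row: interleaved (d/dx_k[j], d/dx_{k+1}[j]) pairs, then u cols
        pairs = np.stack([J_prev, J_next], axis=-1).reshape(self.N - 1, self.n_x,
                                                            2 * self.n_x)
        ddata = np.concatenate([pairs, J_u], axis=-1).ravel() * defect_weight
        data = np.concatenate([self._objective_jac_data(z), ddata])
        J = sparse.csr_matrix((data, (self._jac_rows, self._jac_cols)),
                              shape=(self._n_rows_total, self.n_z))
        return J


def assemble_nlp(system: SkierSystem, ref: ReferenceData,
                 spec: ObjectiveSpec | None = None,
                 grid: CollocationGrid | None = None,
                 bounds: dict | None = None) -> TrackingProblem:
    """Build the collocation NLP (variables, objective, defects, bounds)."""
    return TrackingProblem(system, ref, spec=spec, grid=grid, bounds=bounds)


# ---------------------------------------------------------------------------
# initial guesses

# upright gliding stance: knees soft, the natural pre-turn schuss posture
_UPRIGHT_SCHED = {"hip0": 0.90, "hip_amp": 0.0, "knee0": 1.00, "knee_amp": 0.0}


def make_initial_guess(kind: str, problem: TrackingProblem,
                       v0: float = 11.0) -> np.ndarray:
    """Initial decision vector.

    ``schuss``: forward-simulated straight glide in an upright posture,
    independent of the reference.  ``pd_tracking``: excitation-PD rollout
    tracking the reference channels (the controller's internal least-effort
    redundancy distribution populates consistent muscle states and controls).
    Both are clipped into the variable bounds.
    """
    from .synthetic import ReferenceScheduler, TurnOverlay, _GAINS

    system = problem.system
    grid = problem.grid
    if kind == "schuss":
        overlay = TurnOverlay(steering_window=(0.0, 0.0), max_edging_deg=0.0)
        sched = ReferenceScheduler(system, overlay, v0=v0, sched=_UPRIGHT_SCHED)
        q_des_fn, qd_des_fn = sched.q_des, sched.qd_des
        x0 = sched.initial_state()
    elif kind == "pd_tracking":
        names = system.plane.coordinate_names
        t_ref = problem.ref.channels["time"].to_numpy()

        def q_des_fn(t):
            return np.array([np.interp(t, t_ref, problem.ref.channels[c].to_numpy())
                             if c in problem.ref.channels.columns else 0.0
                             for c in names])

        def qd_des_fn(t):
            return (q_des_fn(t + 0.01) - q_des_fn(max(t - 0.01, 0.0))) / 0.02

        q0 = q_des_fn(0.0)
        qd0 = qd_des_fn(0.0)
        qd0[0] = v0 * np.cos(system.slope_angle)
        qd0[1] = -v0 * np.sin(system.slope_angle)
        x0 = system.initial_state(q0, qd0)
    else:
        raise ValueError(f"unknown initial-guess kind {kind!r}")

    ctrl = ExcitationPD(system, q_des_fn, qd_des_fn=qd_des_fn, gains=_GAINS)
    # roll out at <= 30 ms steps regardless of mesh spacing, then subsample;
    # the schuss glide settles onto its stance first so the recorded window
    # is transient-free
    sub = max(1, int(np.ceil(grid.h / 0.03)))
    dt = grid.h / sub
    if kind == "schuss":
        settle = 1.2
        hold = ExcitationPD(system, lambda t: q_des_fn(0.0), gains=_GAINS)
        xs = x0
        for _ in range(int(round(settle / dt))):
            xs = system.step(xs, np.clip(hold(0.0, xs), 0.0, 1.0), dt).x
        xs = xs.copy()
        xs[1] += np.tan(system.slope_angle) * xs[0]   # restart at x = 0 on the slope
        xs[0] = 0.0
        ctrl.reset()
        x0 = xs
    traj = system.forward_simulate(x0, None, grid.T, dt, controller=ctrl)
    states = traj.states[::sub]
    controls = traj.controls[::sub]
    z = problem.pack_z(states, controls)
    # keep the guess strictly interior: variables pinned on a bound stall the
    # reflective trust-region transform
    margin = 1e-3 * (problem.ub - problem.lb)
    return np.clip(z, problem.lb + margin, problem.ub - margin)


# ---------------------------------------------------------------------------
# solver

def _variable_scales(problem: TrackingProblem) -> np.ndarray:
    """Characteristic step sizes per decision variable for the LM metric."""
    sysm = problem.system
    xs = np.concatenate([
        np.full(sysm.n_q, 0.3),           # coordinates: rad / m
        np.full(sysm.n_q, 1.0),           # rates
        0.1 * sysm.muscles.s_opt,         # projected fiber lengths
        np.full(sysm.n_m, 0.3),           # activations
        np.full(sysm.n_c, 0.005),         # contact memory
    ])
    return np.concatenate([np.tile(xs, problem.N),
                           np.full(problem.N * problem.n_u, 0.3)])


def _lm_minimize(problem: TrackingProblem, z: np.ndarray, rho: float,
                 lam: np.ndarray | None, max_iter: int, damp: float):
    """Scaled Levenberg-Marquardt on the (augmented) penalty least squares.

    Steps solve the damped normal equations with a sparse direct
    factorization; iterates are projected onto the box bounds.  Returns the
    improved point, the last damping and the iteration count.
    """
    scale = _variable_scales(problem)
    D = sparse.diags(scale)
    sr = np.sqrt(rho)
    shift = (lam / rho) if lam is not None else 0.0

    def fun(zz):
        return np.concatenate([problem.objective_residuals(zz),
                               sr * (problem.defects(zz) + shift)])

    r = fun(z)
    cost = 0.5 * float(r @ r)
    stall = 0
    it = 0
    for it in range(1, max_iter + 1):
        J = problem.full_jacobian(z, defect_weight=sr) @ D
        H = (J.T @ J).tocsc()
        g = J.T @ r
        dy = splu(H + damp * sparse.identity(H.shape[0], format="csc")).solve(-g)
        z1 = np.clip(z + scale * dy, problem.lb, problem.ub)
        r1 = fun(z1)
        c1 = 0.5 * float(r1 @ r1)
        pred = -float(g @ dy) - 0.5 * float(dy @ (H @ dy))
        gain = (cost - c1) / max(pred, 1e-16)
        if c1 < cost:
            rel = (cost - c1) / max(cost, 1e-300)
            z, r, cost = z1, r1, c1
            if gain > 0.5:
                damp = max(damp / 3.0, 1e-8)
            stall = stall + 1 if rel < 1e-9 else 0
        else:
            damp = min(damp * 4.0, 1e10)
            stall += 1
        if stall > 8:
            break
    return z, damp, it


def solve_tracking(problem: TrackingProblem, guess: np.ndarray,
                   feas_tol: float = 1e-6, max_outer: int = 6,
                   rho0: float = 30.0, rho_mult: float = 6.0,
                   first_inner_iter: int = 120, inner_iter: int = 50,
                   raise_on_failure: bool = False) -> NLPSolution:
    """Augmented-Lagrangian Levenberg-Marquardt solve of the tracking NLP.

    The merit ``||r_obj||^2 + rho*||c + lam/rho||^2`` is minimized by scaled
    LM with sparse direct normal-equation steps (the defect rows are
    pre-scaled to O(1) by the system residual); the outer loop updates the
    multipliers and increases rho until ``max|defect| <= feas_tol``.

    The solver is a local method: it converges tightly inside a basin of
    attraction but, like any Newton-type method on this nonconvex
    contact-rich NLP, it can terminate at a locally optimal trajectory; the
    reported status distinguishes feasibility ("converged" means the dynamics
    are satisfied at tolerance) from global optimality, which is not
    certified.
    """
    lam = np.zeros((problem.N - 1) * problem.n_x)
    rho = rho0
    z = np.clip(guess, problem.lb, problem.ub)
    damp = 1.0
    status = "max_outer_reached"
    outer = 0
    for outer in range(1, max_outer + 1):
        iters = first_inner_iter if outer == 1 else inner_iter
        z, damp, it = _lm_minimize(problem, z, rho, lam if outer > 1 else None,
                                   iters, max(damp, 1.0))
        c = problem.defects(z)
        feas = float(np.max(np.abs(c)))
        J, tr, ef, rg = problem.objective_parts(z)
        log.info("outer %d: feas=%.3e rho=%.1e J=%.5f (track %.5f effort %.5f reg %.5f) it=%d",
                 outer, feas, rho, J, tr, ef, rg, it)
        if feas <= feas_tol:
            status = "converged"
            break
        lam = lam + rho * c
        rho = min(rho * rho_mult, 1e8)
    X, U = problem.split_z(z)
    J, tr, ef, rg = problem.objective_parts(z)
    sol = NLPSolution(states=X, controls=U, times=problem.grid.times,
                      objective=J, tracking_part=tr, effort_part=ef,
                      regularization_part=rg,
                      constraint_violation=float(np.max(np.abs(problem.defects(z)))),
                      status=status, outer_iterations=outer)
    if not sol.success and raise_on_failure:
        raise SolverError(f"tracking solve did not converge (feas={sol.constraint_violation:.2e})",
                          best=sol)
    return sol


# ---------------------------------------------------------------------------
# sensitivity study

def sensitivity_suite(system: SkierSystem, ref: ReferenceData,
                      variants: list[dict] | None = None,
                      base_spec: ObjectiveSpec | None = None,
                      base_grid: CollocationGrid | None = None,
                      guess_kind: str = "schuss",
                      solver_kwargs: dict | None = None) -> pd.DataFrame:
    """Run tracking solves over objective/mesh/guess variants.

    ``variants`` is a list of override dicts with any of the keys
    ``w2``, ``effort_exponent``, ``n_mesh``, ``guess``; the default list is
    the one-factor-at-a-time program: w2 in {2.5, 5, 10, 20, 40}, effort
    exponent in {2, 3, 5}, mesh in {50, 75, 100, 125}, both initial guesses.
    Individual failures are recorded and the suite continues.
    """
    base_spec = base_spec or ObjectiveSpec()
    base_grid = base_grid or CollocationGrid()
    if variants is None:
        variants = ([{"w2": w} for w in (2.5, 5.0, 10.0, 20.0, 40.0)]
                    + [{"effort_exponent": p} for p in (3, 5)]
                    + [{"n_mesh": n} for n in (50, 100, 125)]
                    + [{"guess": "pd_tracking"}])
    rows = []
    for var in variants:
        spec = ObjectiveSpec(w1=base_spec.w1, w2=var.get("w2", base_spec.w2),
                             w3=base_spec.w3,
                             effort_exponent=var.get("effort_exponent",
                                                     base_spec.effort_exponent))
        grid = CollocationGrid(n_mesh=var.get("n_mesh", base_grid.n_mesh), T=base_grid.T)
        kind = var.get("guess", guess_kind)
        row = {"w2": spec.w2, "effort_exponent": spec.effort_exponent,
               "n_mesh": grid.n_mesh, "guess": kind}
        try:
            problem = assemble_nlp(system, ref, spec=spec, grid=grid)
            z0 = make_initial_guess(kind, problem)
            sol = solve_tracking(problem, z0, **(solver_kwargs or {}))
            q = sol.states[:, :system.n_q]
            ref_vals = ref.resampled(grid.times)
            rmsd = np.sqrt(np.mean((q[:, problem.tracked_idx] - ref_vals) ** 2, axis=0))
            a = sol.states[:, 2 * system.n_q + system.n_m:2 * system.n_q + 2 * system.n_m]
            row.update(objective=sol.objective, tracking_part=sol.tracking_part,
                       effort_part=sol.effort_part,
                       regularization_part=sol.regularization_part,
                       max_rmsd_deg=float(np.rad2deg(np.max(rmsd))),
                       peak_activation=float(np.max(a)),
                       status=sol.status,
                       constraint_violation=sol.constraint_violation)
        except Exception as exc:   # noqa: BLE001 — suite must continue
            row.update(status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)
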