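"""Implicit system residual, forward simulation, energetics."""

import numpy as np
import pytest

from skiturn.dynamics import SkierSystem
from skiturn.planar import PlanarBody, PlanarModel


class TestPlanarEngine:
    def test_free_fall_acceleration(self):
        body = PlanarBody("b", 2.0, 0.1, [0.1, 0.2])
        m = PlanarModel([body])
        qdd = np.linalg.solve(m.mass_matrix(np.zeros(3)),
                              -m.bias_forces(np.zeros(3), np.zeros(3)))
        assert np.allclose(qdd, [0.0, -9.81, 0.0], atol=1e-12)

    def test_inverse_dynamics_matches_symbolic_lagrangian(self, rng):
        """Independent sympy Lagrangian oracle on a free-base 3-link chain."""
        import sympy as sp

        bodies = [
            PlanarBody("root", 5.0, 0.3, [0.1, 0.05]),
            PlanarBody("l1", 2.0, 0.08, [0.02, -0.2], parent="root",
                       pivot_in_parent=[0.05, -0.1]),
            PlanarBody("l2", 1.0, 0.02, [0.0, -0.15], parent="l1",
                       pivot_in_parent=[0.0, -0.4]),
        ]
        pm = PlanarModel(bodies)
        n = pm.ndof
        t = sp.symbols("t")
        qs = [sp.Function(f"q{i}")(t) for i in range(n)]

        def rot(phi, r):
            return sp.Matrix([sp.cos(phi) * r[0] - sp.sin(phi) * r[1],
                              sp.sin(phi) * r[0] + sp.cos(phi) * r[1]])

        p0 = sp.Matrix([qs[0], qs[1]])
        phi0 = qs[2]
        p1 = p0 + rot(phi0, bodies[1].pivot_in_parent)
        phi1 = phi0 + qs[3]
        p2 = p1 + rot(phi1, bodies[2].pivot_in_parent)
        phi2 = phi1 + qs[4]
        T = V = 0
        for b, (po, phi) in zip(bodies, [(p0, phi0), (p1, phi1), (p2, phi2)]):
            c = po + rot(phi, b.com_offset)
            vc = c.diff(t)
            T += b.mass / 2 * (vc.T * vc)[0, 0] + b.inertia / 2 * phi.diff(t) ** 2
            V += b.mass * 9.81 * c[1]
        L = T - V
        eqs = [sp.diff(sp.diff(L, qs[i].diff(t)), t) - sp.diff(L, qs[i])
               for i in range(n)]
        qv = sp.symbols(f"x:{n}")
        qdv = sp.symbols(f"v:{n}")
        qddv = sp.symbols(f"a:{n}")
        subs = {}
        for i in range(n):
            subs[qs[i].diff(t, 2)] = qddv[i]
            subs[qs[i].diff(t)] = qdv[i]
            subs[qs[i]] = qv[i]
        f = sp.lambdify(qv + qdv + qddv, [sp.simplify(e.subs(subs)) for e in eqs])
        for _ in range(5):
            q = rng.normal(size=n)
            qd = rng.normal(size=n)
            qdd = rng.normal(size=n)
            oracle = np.array(f(*q, *qd, *qdd))
            ours = pm.inverse_dynamics(q, qd, qdd)
            assert np.max(np.abs(oracle - ours) / (1 + np.abs(oracle))) < 1e-8

    def test_complex_step_compatible(self):
        body = PlanarBody("b", 2.0, 0.1, [0.1, 0.2])
        child = PlanarBody("c", 1.0, 0.05, [0.0, -0.1], parent="b",
                           pivot_in_parent=[0.0, -0.3])
        m = PlanarModel([body, child])
        q = np.array([0.1, 0.2, 0.3, 0.4], dtype=complex)
        q[3] += 1e-30j
        out = m.inverse_dynamics(q, np.zeros(4), np.zeros(4))
        grad = np.imag(out) / 1e-30
        # cross-check against central differences
        e = np.zeros(4)
        e[3] = 1e-6
        qr = np.real(q)
        fd = (m.inverse_dynamics(qr + e, np.zeros(4), np.zeros(4))
              - m.inverse_dynamics(qr - e, np.zeros(4), np.zeros(4))) / 2e-6
        assert np.allclose(grad, fd, atol=1e-5)


class TestSystemResidual:
    def test_dimension_mismatch_raises(self, system):
        with pytest.raises(ValueError):
            system.system_residual(np.zeros(3), np.zeros(3), np.zeros(2))

    def test_nonfinite_input_raises(self, system):
        x = np.zeros(system.n_x)
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            system.system_residual(x, np.zeros(system.n_x), np.zeros(system.n_u))

    def test_free_fall_demands_gravity_acceleration(self, system):
        """Airborne with slack tendons and zero passive torques: the multibody
        rows vanish exactly when xdot prescribes COM acceleration (0, -g)."""
        names = system.plane.coordinate_names
        q = np.zeros(system.n_q)
        q[1] = 50.0                       # far above the snow
        for j, n in enumerate(names):
            if "knee" in n:
                q[j] = -0.5               # away from the hyperextension stop
            elif "ankle" in n:
                q[j] = system.boot.neutral_angle   # zero boot moment
        qd = np.zeros(system.n_q)
        l_mt, _ = system.muscles.lengths_and_arms(q)
        s_slack = l_mt - 0.95 * system.muscles.l_slack   # tendon shorter than slack: no force
        x = system.pack(q, qd, s_slack, np.zeros(system.n_m), np.zeros(system.n_c))
        xdot = np.zeros(system.n_x)
        xdot[system.n_q + 1] = -9.81      # qdd rows live in the qd slots of xdot
        r = system.residual(x, xdot, np.zeros(system.n_u))
        dyn = r[system.n_q:2 * system.n_q]
        assert np.allclose(dyn, 0.0, atol=1e-6)

    def test_residual_zero_on_fixture_trajectory(self, system, fixture_turn):
        traj = fixture_turn.trajectory
        d = system.defect(traj.states[:-1], traj.states[1:], traj.controls[1:], traj.h)
        assert np.max(np.abs(d)) < 1e-6

    def test_residual_smooth_in_all_arguments(self, system, crouch_state, rng):
        """Complex-step and finite-difference derivatives agree -> C^1."""
        x = crouch_state
        xdot = rng.normal(scale=0.1, size=system.n_x)
        u = rng.uniform(0.05, 0.9, system.n_u)
        for j in rng.integers(0, system.n_x, 6):
            xc = x.astype(complex)
            xc[j] += 1e-30j
            cs = np.imag(system.residual(xc, xdot, u)) / 1e-30
            e = np.zeros(system.n_x)
            e[j] = 1e-6
            fd = (system.residual(x + e, xdot, u) - system.residual(x - e, xdot, u)) / 2e-6
            assert np.allclose(cs, fd, atol=1e-4 * (1 + np.abs(cs).max()))


class TestForwardSimulation:
    def test_invalid_dt_rejected(self, system, crouch_state):
        with pytest.raises(ValueError):
            system.forward_simulate(crouch_state, lambda t: np.zeros(16), 0.1, 0.0)

    def test_schuss_settles_and_stays_symmetric(self, system, crouch_state):
        """Symmetric posture + symmetric controls: left/right stay identical."""
        u_hold = np.full(system.n_u, 0.2)
        traj = system.forward_simulate(crouch_state, lambda t: u_hold, 0.4, 0.02)
        q = traj.states[:, :system.n_q]
        names = system.plane.coordinate_names
        for a, b in (("hip_r_flexion", "hip_l_flexion"),
                     ("knee_r_angle", "knee_l_angle"),
                     ("ankle_r_angle", "ankle_l_angle")):
            ia, ib = names.index(a), names.index(b)
            assert np.allclose(q[:, ia], q[:, ib], atol=1e-8)

    def test_first_order_step_convergence(self, system, crouch_state):
        """Implicit Euler is O(dt): halving dt roughly halves the error."""
        u_hold = np.full(system.n_u, 0.25)
        T = 0.08
        ends = {}
        for dt in (0.02, 0.01, 0.005):
            traj = system.forward_simulate(crouch_state, lambda t: u_hold, T, dt)
            ends[dt] = traj.states[-1, :system.n_q]
        e1 = np.linalg.norm(ends[0.02] - ends[0.005])
        e2 = np.linalg.norm(ends[0.01] - ends[0.005])
        assert e2 < 0.75 * e1     # error shrinks ~linearly with dt

    def test_energy_audit(self, system, crouch_state):
        """dE/dt equals actuation + environment power within 1% of peak power.

        Integrated with the midpoint rule (theta = 0.5), which is
        energy-consistent to second order.
        """
        u_hold = np.full(system.n_u, 0.25)
        dt = 0.004
        traj = system.forward_simulate(crouch_state, lambda t: u_hold, 0.3, dt,
                                       theta=0.5)
        E = system.mechanical_energy(traj.states)
        xd = np.diff(traj.states, axis=0) / dt
        x_mid = 0.5 * (traj.states[1:] + traj.states[:-1])
        P_act, P_env = system.applied_power(x_mid, xd)
        dE = np.diff(E) / dt
        P_tot = P_act + P_env
        peak = np.max(np.abs(P_tot))
        assert np.max(np.abs(dE - P_tot)) < 0.01 * peak


def test_contact_memory_nondecreasing_on_fixture(system, fixture_turn):
    _, _, _, _, mem = system.split(fixture_turn.trajectory.states)
    assert np.all(np.diff(mem, axis=0) >= -1e-9)
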