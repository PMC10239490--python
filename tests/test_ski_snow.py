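"""Segmented ski, hypoplastic penetration, shear, friction, drag, edge geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import root

from skiturn.ski_snow import (AeroParams, ContactKinematics, ContactState, SkiSpec,
                              SnowSurface, air_drag, build_ski,
                              edge_contact_kinematics, friction_force,
                              hypoplastic_normal_force, penetration_force,
                              shear_force)


def _kin(depth=0.0, rate=0.0, edging=0.0, edge_dir=(1, 0, 0), vel=(0, 0, 0),
         normal=(0, 0, 1)):
    return ContactKinematics(penetration_depth=depth, penetration_rate=rate,
                             edging_angle=edging, edge_direction=np.array(edge_dir, float),
                             segment_velocity=np.array(vel, float),
                             surface_normal=np.array(normal, float))


@pytest.fixture
def surf():
    return SnowSurface.inclined_plane(12.3, k_load=50000.0, stiffness_ratio=4.0,
                                      rate_damping=3000.0)


class TestSkiChain:
    def test_nominal_segment_count(self):
        chain, _ = build_ski(SkiSpec())
        assert len(chain.bodies) == 18
        assert chain.ndof == 3 + 17          # free base + 17 internal joints
        assert chain.total_mass == pytest.approx(3.40)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            SkiSpec(n_segments=1)

    def test_zero_camber_equilibrium_is_straight(self):
        spec = SkiSpec(n_segments=5, camber_height=0.0)
        _, moments = build_ski(spec)
        assert np.allclose(moments(np.zeros(4), np.zeros(4)), 0.0)

    def test_unloaded_equilibrium_reproduces_camber(self):
        spec = SkiSpec(n_segments=6, camber_height=0.008)
        _, moments = build_ski(spec)
        theta_c = spec.camber_angles()
        assert np.allclose(moments(theta_c, np.zeros(5)), 0.0, atol=1e-12)
        assert abs(theta_c.sum()) == pytest.approx(8 * 0.008 / spec.length)

    def test_tip_load_static_deflection_matches_torque_balance(self):
        """3-segment ski clamped at the tail: closed-form 2-spring oracle.

        A transverse tip force F at the free end loads joint 1 with moment
        F*(2L + ...) in the small-angle limit; equilibrium angles follow from
        k*theta_i = moment of F about joint i.
        """
        spec = SkiSpec(n_segments=3, camber_height=0.0, bend_stiffness=300.0)
        chain, moments = build_ski(spec)
        L = spec.segment_length
        F = 5.0

        def residual(theta):
            th1, th2 = theta
            # moment of tip force about each joint (small-angle lever arms)
            p1 = np.array([L, 0.0])
            pj2 = p1 + L * np.array([np.cos(th1), np.sin(th1)])
            tip = pj2 + L * np.array([np.cos(th1 + th2), np.sin(th1 + th2)])
            m1 = F * (tip[0] - p1[0])
            m2 = F * (tip[0] - pj2[0])
            k = spec.bend_stiffness
            return [k * th1 - m1, k * th2 - m2]

        oracle = root(residual, [0.01, 0.01], tol=1e-12).x
        # same equilibrium from the chain's passive moments
        def chain_res(theta):
            th1, th2 = theta
            p1 = np.array([L, 0.0])
            pj2 = p1 + L * np.array([np.cos(th1), np.sin(th1)])
            tip = pj2 + L * np.array([np.cos(th1 + th2), np.sin(th1 + th2)])
            m = moments(np.array([th1, th2]), np.zeros(2))
            return [m[0] + F * (tip[0] - p1[0]), m[1] + F * (tip[0] - pj2[0])]

        ours = root(chain_res, [0.01, 0.01], tol=1e-12).x
        assert np.allclose(ours, oracle, atol=1e-10)


class TestPenetrationForce:
    def test_no_contact_no_force_no_memory_change(self, surf):
        state = ContactState(np.array([0.0]))
        f, new = penetration_force(_kin(0.0, 0.0), state, surf, index=0)
        assert f == pytest.approx(0.0, abs=0.1)
        assert new.max_compressed_depth[0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_loading_tracks_virgin_slope_and_memory(self, surf):
        """Incremental oracle: ramp the depth, force nondecreasing, memory == depth."""
        state = ContactState(np.array([0.0]))
        prev = 0.0
        for d in np.linspace(0.001, 0.03, 30):
            f, state = penetration_force(_kin(d, 0.0), state, surf, index=0)
            assert f >= prev - 1e-9
            assert f == pytest.approx(surf.k_load * d, rel=0.05)
            assert state.max_compressed_depth[0] == pytest.approx(d, abs=2e-4)
            prev = f

    def test_unload_reload_hysteresis(self, surf):
        """Load to d*, unload to d*/2, reload: branch force below virgin,
        rejoins the virgin curve at d*, loop work positive."""
        d_star = 0.02
        state = ContactState(np.array([0.0]))
        f_star, state = penetration_force(_kin(d_star), state, surf, index=0)
        f_virgin_half, _ = penetration_force(_kin(d_star / 2),
                                             ContactState(np.array([0.0])), surf, index=0)
        f_reload_half, state = penetration_force(_kin(d_star / 2), state, surf, index=0)
        assert f_reload_half < f_virgin_half          # pre-compressed snow is softer
        f_back, state = penetration_force(_kin(d_star), state, surf, index=0)
        assert f_back == pytest.approx(f_star, rel=1e-6)
        # loop work >= 0 over a closed cycle (rate-independent part)
        depths = np.r_[np.linspace(0, d_star, 25), np.linspace(d_star, 0, 25)]
        state = ContactState(np.array([0.0]))
        forces = []
        for d in depths:
            f, state = penetration_force(_kin(d), state, surf, index=0)
            forces.append(f)
        work = -np.trapezoid(np.asarray(forces), depths)
        assert work <= 1e-9                           # snow dissipates, never returns more
        load_work = np.trapezoid(forces[:25], depths[:25])
        unload_work = -np.trapezoid(forces[25:], depths[25:])
        assert load_work - unload_work >= 0.0

    def test_rate_term_floored_at_zero(self, surf):
        f = hypoplastic_normal_force(0.005, -10.0, 0.005, surf.k_load,
                                     surf.stiffness_ratio, surf.rate_damping)
        assert f >= 0.0


class TestShearForce:
    def test_zero_depth_zero_force(self):
        f = shear_force(_kin(0.0, vel=(0, 1, 0)), 60000.0)
        assert np.linalg.norm(f) == pytest.approx(0.0, abs=0.5)

    def test_proportional_to_depth(self):
        f1 = shear_force(_kin(0.01, vel=(0, 1, 0)), 60000.0)
        f2 = shear_force(_kin(0.02, vel=(0, 1, 0)), 60000.0)
        assert np.linalg.norm(f2) == pytest.approx(2 * np.linalg.norm(f1), rel=1e-3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_orthogonal_to_edge_and_opposing_slip(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        n = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(e, n)) > 0.95:
            return
        v = rng.normal(size=3)
        f = shear_force(_kin(0.01, edge_dir=e, vel=v, normal=n), 60000.0)
        assert abs(np.dot(f, e)) <= 1e-9 * max(np.linalg.norm(f), 1.0)
        lat = np.cross(n, e)
        lat /= np.linalg.norm(lat)
        assert np.dot(f, lat) * np.dot(v, lat) <= 1e-12


class TestFriction:
    def test_coulomb_closed_form(self):
        f = friction_force(1000.0, np.array([10.0, 0.0, 0.0]), mu=0.08)
        assert np.allclose(f, [-80.0, 0.0, 0.0], atol=1e-4)

    def test_zero_velocity_regularized(self):
        f = friction_force(1000.0, np.zeros(3), mu=0.08)
        assert np.allclose(f, 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_always_dissipative(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(scale=5.0, size=3)
        N = abs(rng.normal(scale=800.0))
        assert np.dot(friction_force(N, v), v) <= 1e-12


class TestAirDrag:
    def test_at_rest_no_wind(self):
        assert np.allclose(air_drag(np.zeros(3), AeroParams()), 0.0)

    def test_closed_form_magnitude(self):
        """0.5 * 1.07 * 0.3 * 12^2 = 23.1 N, independently evaluated."""
        f = air_drag(np.array([12.0, 0.0, 0.0]), AeroParams(cda=0.3, rho=1.07))
        assert np.linalg.norm(f) == pytest.approx(0.5 * 1.07 * 0.3 * 144.0, rel=1e-12)
        assert f[0] < 0

    def test_quadratic_in_speed(self):
        f1 = np.linalg.norm(air_drag(np.array([6.0, 0, 0]), AeroParams()))
        f2 = np.linalg.norm(air_drag(np.array([12.0, 0, 0]), AeroParams()))
        assert f2 == pytest.approx(4 * f1, rel=1e-12)


class TestEdgeContactKinematics:
    spec = SkiSpec()

    def test_flat_ski_on_flat_snow(self):
        surf = SnowSurface.inclined_plane(0.0)
        kin = edge_contact_kinematics(np.zeros(3), np.eye(3), np.zeros(3),
                                      np.zeros(3), surf, self.spec)
        assert kin.edging_angle == pytest.approx(0.0, abs=1e-9)
        assert kin.penetration_depth == pytest.approx(0.0, abs=1e-9)

    def test_rolled_ski_edging_angle(self):
        surf = SnowSurface.inclined_plane(0.0)
        a = np.deg2rad(30)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        kin = edge_contact_kinematics(np.array([0, 0, 1.0]), R, np.zeros(3),
                                      np.zeros(3), surf, self.spec)
        assert np.rad2deg(kin.edging_angle) == pytest.approx(30.0, abs=1e-9)

    def test_side_cut_sagitta_matches_circle_geometry(self):
        """Half-width at mid-ski vs tip differs by the exact arc sagitta."""
        R, L = self.spec.side_cut_radius, self.spec.length
        sagitta = R - np.sqrt(R**2 - (L / 2) ** 2)
        w_mid = self.spec.side_cut_half_width(0.0)
        w_tip = self.spec.side_cut_half_width(L / 2)
        assert w_tip - w_mid == pytest.approx(sagitta, rel=1e-12)


def test_airborne_ski_has_no_contact_forces(system):
    """All contact forces vanish identically with every point above the snow."""
    q = np.zeros(system.n_q)
    q[1] = 5.0      # pelvis 5 m above the surface
    qd = np.zeros(system.n_q)
    qd[0] = 10.0
    x = system.pack(q, qd, system.muscles.s_opt.copy(),
                    np.zeros(system.n_m), np.zeros(system.n_c))
    qq, qdq, s, a, mem = system.split(x)
    kin = system.plane.kinematics(qq, qdq)
    depths, rates, f_n, loads = system.contact_terms(kin, qq, mem)
    for f in f_n:
        assert abs(f) < 1e-6
    for _, _, force, _ in loads:
        assert np.allclose(force, 0.0, atol=1e-6)
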