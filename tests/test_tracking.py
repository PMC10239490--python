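"""Collocation transcription, objective closed forms, solver machinery."""

import numpy as np
import pytest

from skiturn import tracking as trk
from skiturn.control import static_redundancy_activations
from skiturn.dynamics import SkierSystem


@pytest.fixture(scope="module")
def ref(system, fixture_turn):
    return trk.ReferenceData.from_fixture(fixture_turn, system)


@pytest.fixture(scope="module")
def problem(system, ref):
    return trk.assemble_nlp(system, ref)


class TestImplicitEulerStep:
    def test_scalar_decay_closed_form(self):
        """x' = -x, h = 0.1, x_k = 1: the defect root is 1/1.1."""
        h, xk = 0.1, 1.0

        def defect(x_next):
            return (x_next - xk) / h + x_next     # f(x, xdot) = xdot + x

        from scipy.optimize import brentq
        root = brentq(defect, 0.0, 2.0)
        assert root == pytest.approx(1.0 / 1.1, abs=1e-12)

    def test_defects_vanish_on_forward_simulated_trajectory(self, system, fixture_turn):
        grid = trk.CollocationGrid(n_mesh=75, T=2.0)
        defects = trk.discretize_dynamics(system, grid)
        traj = fixture_turn.trajectory
        d = defects(traj.states, traj.controls)
        assert np.max(np.abs(d)) < 1e-6

    def test_local_truncation_error_first_order(self, system, crouch_state):
        """Halving h halves the one-step mismatch of the coarse defect on a
        fine trajectory (order consistency of the implicit Euler formula)."""
        u = np.full(system.n_u, 0.25)
        fine = system.forward_simulate(crouch_state, lambda t: u, 0.08, 0.005)
        errs = {}
        for stride in (4, 2):       # coarse steps h = stride * 0.005
            h = stride * 0.005
            d = system.defect(fine.states[:-stride:stride], fine.states[stride::stride],
                              u, h)
            errs[stride] = np.max(np.abs(d))
        assert errs[2] < 0.75 * errs[4]


class TestObjective:
    def test_zero_at_perfect_tracking_with_zero_effort(self, system, ref):
        spec = trk.ObjectiveSpec()
        prob = trk.assemble_nlp(system, ref, spec=spec)
        X = np.zeros((prob.N, prob.n_x))
        X[:, prob.tracked_idx] = prob.ref_values
        # constant states, zero activations, constant controls
        U = np.zeros((prob.N, prob.n_u))
        # make untracked states constant in time so the regularization vanishes
        X[:, :] = X[0, :]
        X[:, prob.tracked_idx] = prob.ref_values[0]
        prob2 = trk.assemble_nlp(system, ref, spec=spec)
        prob2.ref_values = np.tile(prob.ref_values[0], (prob.N, 1))
        J, tr, ef, rg = prob2.objective_parts(prob2.pack_z(X, U))
        assert J == pytest.approx(0.0, abs=1e-20)

    def test_single_channel_constant_error_closed_form(self, system, ref):
        """One tracked channel off by a constant normalized error e:
        J = w1 * e^2 / n_d (rectangle rule over the full horizon)."""
        spec = trk.ObjectiveSpec(w2=0.0, w3=0.0)
        prob = trk.assemble_nlp(system, ref, spec=spec)
        X = np.zeros((prob.N, prob.n_x))
        X[:, prob.tracked_idx] = prob.ref_values
        err_rad = np.deg2rad(5.0)
        j_knee = list(prob.tracked_idx).index(
            system.plane.coord_index("knee_r_angle"))
        X[:, prob.tracked_idx[j_knee]] += err_rad
        U = np.zeros((prob.N, prob.n_u))
        J, tr, _, _ = prob.objective_parts(prob.pack_z(X, U))
        n_d = len(prob.tracked_idx)
        e = err_rad / spec.angle_scale
        # right-endpoint rectangle rule covers (N-1)/N... exactly h*(N-1)/T = 1
        assert tr == pytest.approx(spec.w1 * e**2 / n_d, rel=1e-9)

    def test_constant_half_activation_effort_closed_form(self, system, ref):
        """a = 0.5 everywhere, p = 2: effort part = w2 * 0.25."""
        spec = trk.ObjectiveSpec(w1=0.0, w3=0.0, w2=10.0)
        prob = trk.assemble_nlp(system, ref, spec=spec)
        X = np.zeros((prob.N, prob.n_x))
        a0 = 2 * system.n_q + system.n_m
        X[:, a0:a0 + system.n_m] = 0.5
        U = np.zeros((prob.N, prob.n_u))
        J, _, ef, _ = prob.objective_parts(prob.pack_z(X, U))
        assert ef == pytest.approx(spec.w2 * 0.25, rel=1e-9)

    def test_parts_sum_to_objective(self, problem, fixture_turn):
        z = problem.pack_z(fixture_turn.trajectory.states,
                           fixture_turn.trajectory.controls)
        J, tr, ef, rg = problem.objective_parts(z)
        assert J == pytest.approx(tr + ef + rg, rel=1e-12)
        assert min(tr, ef, rg) >= 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            trk.ObjectiveSpec(w1=-1.0)
        with pytest.raises(ValueError):
            trk.ObjectiveSpec(effort_exponent=1.0)


class TestAssembly:
    def test_variable_and_constraint_counts(self, system, ref):
        grid = trk.CollocationGrid(n_mesh=2, T=0.05)
        prob = trk.assemble_nlp(system, ref, grid=grid)
        nodes = 2
        assert prob.n_z == nodes * (system.n_x + system.n_u)
        assert prob.defects(np.zeros(prob.n_z) + 0.5).size == (nodes - 1) * system.n_x

    def test_infeasible_bounds_rejected(self, system, ref):
        with pytest.raises(ValueError, match="bounds"):
            trk.assemble_nlp(system, ref, bounds={"activation": [1.0, 0.0]})

    def test_jacobian_matches_finite_differences(self, problem, fixture_turn, rng):
        """Exact complex-step Jacobian vs central differences on random
        directions (FD-limited agreement)."""
        z = problem.pack_z(fixture_turn.trajectory.states,
                           fixture_turn.trajectory.controls)
        J = problem.full_jacobian(z, defect_weight=1.0)

        def full_res(zz):
            return np.concatenate([problem.objective_residuals(zz),
                                   problem.defects(zz)])

        worst = 0.0
        for j in rng.integers(0, problem.n_z, 10):
            dz = 1e-6 * max(1.0, abs(z[j]))
            zp, zm = z.copy(), z.copy()
            zp[j] += dz
            zm[j] -= dz
            fd = (full_res(zp) - full_res(zm)) / (2 * dz)
            an = np.asarray(J[:, j].todense()).ravel()
            worst = max(worst, np.max(np.abs(fd - an)) / max(1.0, np.max(np.abs(fd))))
        assert worst < 1e-5

    def test_initial_guesses_respect_bounds(self, problem):
        for kind in ("schuss", "pd_tracking"):
            z = trk.make_initial_guess(kind, problem)
            assert np.all(z >= problem.lb)
            assert np.all(z <= problem.ub)

    def test_schuss_guess_is_a_straight_glide(self, problem, system):
        z = trk.make_initial_guess("schuss", problem)
        X, _ = problem.split_z(z)
        knee = X[:, system.plane.coord_index("knee_r_angle")]
        # posture held up to slow trim drift with speed: no turn maneuver
        assert np.ptp(knee) < np.deg2rad(15.0)

    def test_unknown_guess_kind_rejected(self, problem):
        with pytest.raises(ValueError):
            trk.make_initial_guess("warp", problem)


class TestSolver:
    def test_warm_start_at_reference_stays_and_tightens(self, system, ref, fixture_turn):
        """Started at the (feasible) reference the solver must stay in its
        neighborhood: the tracking error remains small while feasibility
        tightens — the acid test that transcription and solver agree."""
        prob = trk.assemble_nlp(system, ref)
        z0 = np.clip(prob.pack_z(fixture_turn.trajectory.states,
                                 fixture_turn.trajectory.controls),
                     prob.lb, prob.ub)
        sol = trk.solve_tracking(prob, z0, max_outer=2, first_inner_iter=40,
                                 inner_iter=20)
        err = sol.states[:, prob.tracked_idx] - prob.ref_values
        max_rmsd = np.rad2deg(np.sqrt(np.mean(err[:, 2:] ** 2, axis=0))).max()
        assert max_rmsd < 2.5
        assert sol.constraint_violation < 5e-3
        # re-evaluating the defects outside the NLP must agree
        d = system.defect(sol.states[:-1], sol.states[1:], sol.controls[1:],
                          prob.grid.h)
        assert np.max(np.abs(d)) == pytest.approx(sol.constraint_violation, rel=1e-9)

    def test_solution_respects_excitation_bounds(self, system, ref, fixture_turn):
        prob = trk.assemble_nlp(system, ref)
        z0 = np.clip(prob.pack_z(fixture_turn.trajectory.states,
                                 fixture_turn.trajectory.controls),
                     prob.lb, prob.ub)
        sol = trk.solve_tracking(prob, z0, max_outer=1, first_inner_iter=15)
        assert np.all(sol.controls >= 0.0)
        assert np.all(sol.controls <= 1.0)


class TestEffortExponent:
    def test_higher_exponent_balances_synergists(self):
        """Two-synergist toy: one joint moment shared by muscles of unequal
        capacity; the min-sum(u^p) split is u1/u2 = (c1/c2)^(1/(p-1)), so
        raising p evens out the distribution."""
        from skiturn.control import least_effort_distribution

        A = np.array([[50.0, 30.0]])    # capacities c = arm * f_max
        tau = np.array([20.0])
        ratios = {}
        for p in (2.0, 3.0, 5.0):
            u = least_effort_distribution(A, tau, exponent=p)
            assert A @ u == pytest.approx(tau, rel=1e-6)
            ratios[p] = u[0] / u[1]
            assert ratios[p] == pytest.approx((50 / 30) ** (1 / (p - 1)), rel=1e-3)
        assert ratios[5.0] < ratios[3.0] < ratios[2.0]

    def test_static_redundancy_matches_torque_demand(self, system):
        """The per-node redundancy solve reproduces the requested torques."""
        joint_idx = list(range(3, system.n_q))
        q = np.zeros(system.n_q)
        tau = np.zeros(len(joint_idx))
        tau[system.plane.coordinate_names.index("knee_r_angle") - 3] = 60.0
        a = static_redundancy_activations(system, q, tau, joint_idx)
        assert np.all(a >= 0) and np.all(a <= 1)
        iv = system.muscles.names.index("vasti_r")
        assert a[iv] > 0.01    # the knee extensors carry the demand


def test_sensitivity_table_has_one_row_per_variant(system, ref):
    """Bookkeeping only: failures are recorded, no duplicates."""
    variants = [{"w2": 5.0, "n_mesh": 8}, {"w2": 10.0, "n_mesh": 8}]
    table = trk.sensitivity_suite(system, ref, variants=variants,
                                  base_grid=trk.CollocationGrid(n_mesh=8, T=2.0),
                                  solver_kwargs={"max_outer": 1,
                                                 "first_inner_iter": 3})
    assert len(table) == 2
    assert not table.duplicated(subset=["w2", "effort_exponent", "n_mesh", "guess"]).any()
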