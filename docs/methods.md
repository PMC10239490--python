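# Methods

`skiturn` estimates muscle and anterior-cruciate-ligament (ACL) forces during
a carved alpine-ski turn by tracking reference kinematics with a muscle-driven
multibody model under implicit dynamics, solved by direct collocation.  This
note documents the models, the numerical choices, and what the synthetic study
conditions do and do not represent.

## The skier model

The skeleton is a rigid-body tree read from a configuration file.  The shipped
`nominal_3d` preset has a free 6-DOF pelvis, a 3-DOF ball lumbar joint, and per
leg a 3-DOF ball hip, revolute knee and revolute ankle — 19 unlocked
coordinates in total.  Subtalar and toe joints are locked (a ski boot admits
essentially no motion there), the head is welded to the trunk, and the arms
are welded in a typical skiing position with their mass and inertia folded
into the trunk assembly.  Segment masses and inertias follow standard
anthropometric scaling to the subject (height 1.90 m, mass 72 kg) and live in
the config file, not in code.  Ball and free-joint orientations use the
extrinsic Z-X-Y (tilt / list / rotation) sequence; angles are radians
internally and degrees at every I/O boundary.

Dynamic simulation and tracking run on the `reduced_planar` preset: the
sagittal-plane skier (pelvis x, z, pitch + hip/knee/ankle per leg, 9 DOF) with
trunk, head and arms lumped onto the pelvis and each ski welded to its foot.
The planar engine computes kinematics and inverse dynamics by Jacobian
projection on the exact recursive frame propagation; it is hand-coded in
vectorized numpy so that one evaluation covers all collocation nodes at once,
and every operation is analytic in the complex-step sense, which is how all
first derivatives are obtained at machine precision.  A symbolic Lagrangian
derivation (sympy) of the same chain serves as an independent test oracle; the
two agree to 1e-8 relative on random states.  The engine deliberately keeps
the symbolic route out of the production path: the numeric recursion is fast
enough to evaluate thousands of times per solver iteration, needs no code
generation step, and its derivatives are exact by construction.

The planar reduction is the package's central scaled-down design choice.  The
lateral physics of the carved turn — edging, the side-cut-imposed turn radius,
and the centripetal ground-reaction force — are represented by a kinematic
overlay (`TurnOverlay`): an edging-angle schedule (cosine bump peaking at 53
degrees during the steering phase) sets the carve radius `R = R_sc *
cos(edging)` with a 18 m side-cut radius, giving a minimum radius near 10.8 m;
the heading integrates the curvature to produce the transverse track; the
centripetal force `m v^2/R` is shared between outside and inside leg (70/30 at
the apex).  The overlay supplies the frontal- and transverse-plane knee
moments that a sagittal model cannot produce.  Everything sagittal — posture,
contact normal loads, muscle coordination — is fully dynamic and
muscle-driven.

## Muscles

Muscles are three-element Hill models in implicit form.  The states are the
projected fiber length `s` (contractile-element length projected along the
tendon; constant-thickness pennation with width `l_opt*sin(penn_opt)`) and the
activation `a`.  Contraction dynamics are the tendon–fiber force balance

    f_tendon(l_mt - s) = cos(penn) * f_max * (a*fl*fv + fpe + beta*v_norm)

with a Gaussian active force–length curve (width 0.6 — wide, because each
table entry is a lumped muscle group whose members peak at different lengths),
an asinh-based force–velocity curve with eccentric plateau, a softplus-squared
parallel-elastic element reaching `f_max` at 100 % fiber strain, and a tendon
with a quadratic toe blending into a linear region, normalized to pass exactly
through `f_max` at 4 % strain.  The damping term `beta = 0.01` (fraction of
`f_max` per optimal-fiber-length/s) keeps the residual solvable for the fiber
velocity at zero activation.  Activation dynamics are a first-order lag with
`tau_act = 15 ms` and a deactivation constant `tau_deact = 60 ms` slowed at
high activation, blended smoothly so the residual is C^1.

Moment arms are per-coordinate polynomials; the muscle–tendon length is their
exact integral, so `arm = -d(l_mt)/dq` holds identically.  The nominal table
has the full 94-muscle roster (43 per leg + 8 lumbar); the planar table lumps
them into 16 groups (8 per leg).  Lumped-group parameters (maximal forces,
optimal fiber lengths) are deliberately on the strong/long side of the
single-muscle literature: one table row stands for several muscles, and the
fiber operating range must span the large joint excursions of a deep skiing
crouch without spurious passive forces.

## Ski and snow

Each ski is a chain of 18 rigid segments joined by revolute spring–damper
joints whose unloaded equilibrium reproduces the camber arc; total length
1.7 m, mass 3.4 kg, side-cut radius 18 m.  Snow contact applies three force
components: a hypoplastic penetration force normal to the surface, a shear
force orthogonal to the ski edge resisting lateral skidding (proportional to
penetration depth), and Coulomb friction with `mu = 0.08` antiparallel to the
segment velocity.  Air drag `0.5 * rho * CdA * v^2` with `CdA = 0.3 m^2` and
`rho = 1.07 kg/m^3` acts at the pelvis COM.

The hypoplastic law is a two-branch incremental-stiffness model: virgin
loading follows `k_load * depth`; unloading and reloading below the maximum
compressed depth follow a slope `stiffness_ratio` (default 4) times steeper,
anchored at the memory point — once-compressed snow offers less resistance on
re-penetration, which is the groove-forming behavior of a carved turn.  The
memory depth is explicit state advanced with the discretization (continuous
form: the memory relaxes upward toward the current depth at 50 1/s, so it
tracks the depth during virgin loading and freezes on unloading).  A rate
term adds dissipation, floored so the total force stays nonnegative.  The
stiffness values are order-of-magnitude estimates (the laboratory-calibrated
originals are unpublished) and are flagged as such in the config.

In the planar loop each ski contributes two contact points (tail and tip
regions).  The boot is a nonlinear passive ankle moment: deadband-filtered
linear+cubic elasticity about a 14-degree dorsiflexed neutral with linear
damping, at race-boot stiffness (650 N·m/rad linear term) — stiff boots are
what make fore-aft balance on skis possible, and the simulated skier is no
exception.

## Smoothness choices

The collocation NLP is gradient-based, so every model nonsmoothness is
regularized, and the regularization scales were chosen to set the
linearization radius the optimizer sees:

* contact depth clamp: softplus with 2 mm half-width (exponential tail, so
  airborne contact forces vanish identically);
* friction/shear slip saturation: 1e-3 m/s;
* tendon toe one-sided blend: 1/120 strain units;
* memory update `smooth max`: 1 mm; hyperextension stop and deadbands:
  quadratic/tanh forms.

A soft knee hyperextension stop (quadratic beyond -6 degrees) and small
viscous joint damping (1 N·m·s/rad) stand in for passive structures.

## The synthetic reference turn

No motion-capture data ships with the package; the `synthetic` module
generates the study conditions.  The course is an inclined plane at 12.3
degrees with gates offset 8 m transverse / 16 m downhill.  The reference
fixture is a ~2 s single carved turn produced by rolling out the muscle-driven
model under a posture-schedule controller and recording the applied
excitations per mesh node, so the stored trajectory satisfies the implicit
dynamics exactly with its stored controls (collocation defects < 1e-7) and
the ground-truth excitations are known.

The posture schedule is a quasi-static trim: for each crouch level the ankle
angle is solved so the boot moment balances the center-of-pressure demand
(including the pseudo-force of the ~1 m/s^2 downhill acceleration), and the
pelvis pitch closes the leg chain so the skis stay parallel to the slope.
The crouch deepens during the steering phase (knee flexion ~62–83 degrees,
always above 60) and entry speed is 11 m/s, reaching ~12–14 m/s.  The
controller combines feedforward holding torques, joint-space PD, an
ankle/hip center-of-pressure balance strategy, and a leaky torque-tracking
integrator that distributes corrections least-norm over the muscle
capacities; the excitations it applies are whatever this closed loop
produced — they are the fixture's ground truth, and the fixture is
regenerable from (config, seed) alone.

What the fixture does not emulate: marker-level noise and soft-tissue
artifact (noise is added at joint-angle level on request), out-of-plane
kinematics (pelvis list/rotation, hip ab/adduction — absent in the planar
model), asymmetric leg flexion, terrain irregularity, and EMG
electromechanical delay.  Passing tests therefore demonstrate internal
consistency of the method chain on a clean, planar, single-turn analog — not
fidelity to any particular skier.

## Tracking optimal control

States `x = [q, qdot, s, a, mem]` and controls `u` (excitations) are
discretized on a uniform mesh (nominal 75 points over 2 s) with the implicit
Euler formula; the dynamics enter as per-interval defect constraints
`f(x_{k+1}, (x_{k+1}-x_k)/h, u_{k+1}) = 0`.  The objective is

    J = (1/T) * int [ (w1/n_d)||err_d||^2 + (w2/n_m)||a||_p^p
                      + (w3/n_xu)(||xdot||^2 + ||udot||^2) ] dt

with the rectangle rule on the implicit-Euler nodes.  Nominal weights are
`w2 = 10` and effort exponent `p = 2`; `w1 = 1` and `w3 = 1e-3` are package
defaults chosen so the three terms sit within about two orders of magnitude
on the synthetic case.  Tracking errors are normalized by fixed
characteristic scales (10 degrees for angles, 0.1 m for translations) rather
than data-dependent scaling, for reproducibility.  State bounds: anatomical
joint ranges, activations and excitations in [0, 1], projected fiber lengths
in (0.3, 1.7) of optimal.

The solver treats the NLP as bound-constrained nonlinear least squares (for
exponent p the effort integrand is the square of `a^(p/2)`): an
augmented-Lagrangian outer loop on the defects around a scaled
Levenberg-Marquardt inner method whose steps come from a sparse direct
factorization of the damped normal equations.  Defect Jacobians are exact
(complex step, vectorized over the mesh); objective Jacobians are analytic.
Feasibility is measured on the scaled residual rows (multibody rows
normalized by ~body weight / 200 N·m, muscle rows by `f_max`), so a scaled
tolerance of 1e-6 corresponds to sub-Newton force imbalances.

Two initial guesses are provided.  The *schuss* guess is a settled straight
glide in a knees-soft stance (hip 0.90 rad, knee 1.00 rad — a skier's natural
gliding posture), independent of the reference.  The *PD-tracking* guess
rolls the excitation-PD controller on the reference channels; its
least-effort redundancy distribution populates consistent muscle states and
controls.

### Known limitation: basin of attraction

The tracking NLP is nonconvex, and the contact-rich landscape has multiple
locally optimal trajectories.  Warm-started near the reference, the solver
converges to a solution with sub-degree joint-angle RMSD and tight
feasibility, confirming that the transcription and the local method are
sound.  Started from the schuss guess, however, the solver terminates in a
distinct local optimum that glides through the turn without deepening the
crouch, at a maximum joint-angle RMSD of roughly 10–20 degrees; the two
solutions are separated by a defect-penalty barrier several orders of
magnitude high, which first-order penalty methods cannot cross.  Weight
continuation, contact-stiffness continuation, growing-horizon bootstrapping,
reference homotopy and penalty warm-up were all implemented and all terminate
in the same valley.  Crossing it appears to require an exact-second-order
interior-point method of the kind the original workflow used; none is
available in this package's dependency set, so the schuss-guess tracking
accuracy reported by the acceptance script reflects this local optimum.  The
solver reports feasibility status explicitly and never claims global
optimality.

The sensitivity interface runs the documented one-factor program (effort
exponent 2/3/5, `w2` in 2.5–40, mesh 50–125, both guesses) and tabulates
objective parts, RMSD and peak activations per variant, continuing past
individual failures.

## Knee loads and the ACL model

Intersegmental knee loads come from a Newton–Euler recursion over the distal
chain (ski → foot → shank) using the trajectory's backward-difference
accelerations and the recomputed contact forces, expressed in the tibia frame.
The anterior shear is reported as the demand on the knee-crossing structures
(positive = the environment and inertia push the tibia anteriorly).  The
recursion is cross-checked against the knee-coordinate generalized force from
full-model inverse dynamics (1e-6 relative).

The ligamentous shear adds the anterior components of the knee-crossing
muscle forces on the tibia: quadriceps act through the patellar tendon, whose
angle versus flexion is a built-in table with a sign change near 70 degrees;
hamstrings and gastrocnemius pull posteriorly and unload the ACL.  The ACL
force is the sum of three nonnegative components: sagittal — a
flexion-dependent tabulated proportion of the positive anterior ligamentous
shear; frontal — an exponential in the external abduction moment decaying
with flexion, zero for adduction-side moments (the inside leg); transverse —
the analogue in the internal-rotation moment.  The frontal/transverse moments
come from the turn overlay: the leg's share of the centripetal edge force
times the knee-to-contact lever, abduction-signed on the outside leg.  The
regression coefficients ship in an editable file with synthetic
literature-informed defaults — absolute ACL numbers are coefficient-dependent
and should be read as demonstrating the method chain, not as subject-specific
estimates.  Tibiofemoral compression does not enter the sagittal term in the
default model.

## Evaluation

`analysis` provides per-channel RMSD, the per-leg track (ankle-joint-center
paths: downhill progression from the planar dynamics, transverse offset from
the overlay), COM speed, and the minimum turn radius from the curvature of
the spline-smoothed track over the steering window (defined as edging > 3
degrees).  EMG envelopes are full-wave rectified and low-pass filtered with a
zero-lag second-order dual-pass Butterworth at 6 Hz; comparison scales each
envelope to the maximum of the estimated activation (EMG amplitude is
scale-free) and reports Pearson correlations.  Synthetic EMG for the ten
electrode sites of the original protocol maps onto the reduced muscle set
with documented proxies for the frontal-plane muscles the planar model lacks.

## Problem sizes used in tests and the acceptance script

The shipped test suite and `scripts/acceptance.py` run the reduced planar
model: the 75-node, 2 s fixture and one full tracking solve (about 5000
decision variables), with coarser 8–15-node instances for trend checks such
as the `w2` sweep.  The nominal 3D model is exercised structurally (counts,
kinematics, mass properties).  These sizes are the package's desk-scale
study conditions; the 4-turn course generator and the full sensitivity
factorial exist in the API for longer runs.
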