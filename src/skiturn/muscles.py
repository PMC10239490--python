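"""Three-element Hill-type muscles in implicit form.

State per muscle: the projected fiber length ``s`` (contractile-element length
projected along the tendon line; pennation is a constant-thickness model with
width ``w = l_opt*sin(penn_opt)``) and the activation ``a``.  Both contraction
and activation dynamics are expressed as residuals, so the collocation
transcription and the forward-simulation root solver share one code path.

Curve shapes (active force-length Gaussian, asinh-based force-velocity with an
eccentric plateau, quadratic-toe tendon, softplus-squared parallel-elastic) are
smooth and complex-step differentiable; their constants live on
:class:`MuscleSpec` and are config-overridable.  Moment arms are per-coordinate
polynomials; the muscle-tendon length is their exact integral, so
``arm == -d(l_mt)/dq`` holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import load_muscle_table, parse_moment_arms

# force-velocity curve constants (normalized; concentric < 1 < eccentric)
_FV_D1, _FV_D2, _FV_D3, _FV_D4 = -0.318, -8.149, -0.374, 0.886
_FV_NORM = _FV_D1 * np.arcsinh(_FV_D3) + _FV_D4  # value at zero velocity


@dataclass
class MuscleSpec:
    name: str
    f_max: float                 # N
    l_opt: float                 # m, optimal fiber length
    l_slack: float               # m, tendon slack length
    penn_opt: float = 0.0        # rad, pennation at optimal fiber length
    tau_act: float = 0.015       # s
    tau_deact: float = 0.060     # s
    moment_arm_coeffs: dict[str, list[float]] = field(default_factory=dict)
    l_mt0: float | None = None   # muscle-tendon length at q = 0 (default: slack + optimal projection)
    fl_width: float = 0.60       # Gaussian width of active force-length (wide: lumped muscle groups)
    v_max: float = 10.0          # optimal fiber lengths per second
    tendon_strain_at_fmax: float = 0.04
    damping: float = 0.01        # normalized fiber damping (fraction of f_max per l_opt/s)

    def __post_init__(self):
        if self.f_max <= 0 or self.l_opt <= 0 or self.l_slack < 0:
            raise ValueError(f"muscle {self.name!r}: invalid f_max/l_opt/l_slack")
        if not 0 < self.tau_act <= self.tau_deact:
            raise ValueError(f"muscle {self.name!r}: need 0 < tau_act <= tau_deact")
        if self.l_mt0 is None:
            self.l_mt0 = self.l_slack + self.l_opt * np.cos(self.penn_opt)

    @property
    def width(self) -> float:
        """Constant fiber-thickness offset l_opt*sin(penn_opt)."""
        return self.l_opt * np.sin(self.penn_opt)

    @property
    def s_opt(self) -> float:
        """Projected fiber length when the fiber is at optimal length."""
        return self.l_opt * np.cos(self.penn_opt)

    @property
    def spanned_coordinates(self) -> list[str]:
        return list(self.moment_arm_coeffs)


def load_muscles(table: str | pd.DataFrame) -> list[MuscleSpec]:
    df = load_muscle_table(table) if isinstance(table, str) else table
    out = []
    for _, row in df.iterrows():
        out.append(MuscleSpec(
            name=row["name"], f_max=float(row["f_max"]), l_opt=float(row["l_opt"]),
            l_slack=float(row["l_slack"]), penn_opt=float(row["penn_opt"]),
            tau_act=float(row["tau_act"]), tau_deact=float(row["tau_deact"]),
            moment_arm_coeffs=parse_moment_arms(row["moment_arms"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Hill curves (normalized)

def active_force_length(lf_norm, width: float = 0.60):
    d = (lf_norm - 1.0) / width
    return np.exp(-d * d)


def force_velocity(v_norm):
    """Normalized force-velocity; v_norm > 0 is lengthening (eccentric)."""
    z = _FV_D2 * v_norm + _FV_D3
    return (_FV_D1 * np.arcsinh(z) + _FV_D4) / _FV_NORM


def passive_force_length(lf_norm, strain_at_fmax: float = 1.0, sharpness: float = 30.0):
    """Parallel-elastic force: ~0 below optimal length, 1 at 1+strain_at_fmax."""
    z = np.asarray((lf_norm - 1.0) * sharpness)
    sp = np.where(np.real(z) > 30.0, z, np.log1p(np.exp(np.where(np.real(z) > 30.0, 0.0, z)))) / sharpness
    return (sp / strain_at_fmax) ** 2


def _tendon_raw(eps, eps_toe, sharpness: float = 120.0):
    """Unit-scale tendon curve: smooth one-sided strain, quadratic toe, linear."""
    z = np.asarray(eps * sharpness)
    sp = np.where(np.real(z) > 30.0, z,
                  np.log1p(np.exp(np.where(np.real(z) > 30.0, 0.0, z)))) / sharpness
    toe = sp * sp
    lin = eps_toe**2 + 2.0 * eps_toe * (sp - eps_toe)
    return np.where(np.real(sp) <= eps_toe, toe, lin)


def tendon_force(l_tendon, spec: MuscleSpec):
    """Series-elastic force (N): quadratic toe then linear, zero in slack.

    The curve is normalized so the force is exactly f_max at the nominal
    strain, independent of the toe smoothing.
    """
    eps = l_tendon / spec.l_slack - 1.0
    eps_toe = spec.tendon_strain_at_fmax / 2.0
    norm = _tendon_raw(spec.tendon_strain_at_fmax, eps_toe)
    return spec.f_max * _tendon_raw(eps, eps_toe) / norm


# ---------------------------------------------------------------------------
# Implicit dynamics

def activation_residual(a, adot, u, spec: MuscleSpec):
    """First-order activation dynamics residual (1/s): zero iff adot matches.

    Activation is faster than deactivation; the two time scales are blended
    smoothly in (u - a) so the residual stays differentiable for the NLP.
    Steady state is a == u.
    """
    blend = 0.5 + 0.5 * np.tanh(40.0 * (u - a))
    rate_act = blend / spec.tau_act
    rate_deact = (1.0 - blend) * (0.5 + 1.5 * a) / spec.tau_deact
    return adot - (rate_act + rate_deact) * (u - a)


def fiber_geometry(s, spec: MuscleSpec):
    """(fiber length, cos pennation) from the projected fiber length."""
    w = spec.width
    lf = np.sqrt(s * s + w * w)
    return lf, s / lf


def contraction_residual(s, sdot, a, l_mt, spec: MuscleSpec):
    """Tendon-fiber force-balance residual (normalized by f_max) and tendon force.

    residual == 0 enforces f_tendon == cos(penn) * f_max *
    (a*fl(lf)*fv(vf) + fpe(lf) + damping*vf_norm).  The damping term keeps the
    residual solvable for ``sdot`` at a == 0.
    """
    lf, cos_p = fiber_geometry(s, spec)
    lf_dot = s * sdot / lf
    v_norm = lf_dot / (spec.l_opt * spec.v_max)
    fl = active_force_length(lf / spec.l_opt, spec.fl_width)
    fv = force_velocity(v_norm)
    fpe = passive_force_length(lf / spec.l_opt)
    f_fiber = (a * fl * fv + fpe + spec.damping * lf_dot / spec.l_opt) * spec.f_max
    f_t = tendon_force(l_mt - s, spec)
    return (f_t - cos_p * f_fiber) / spec.f_max, f_t


# ---------------------------------------------------------------------------
# Geometry: muscle-tendon length and moment arms

def muscle_tendon_length_and_moment_arms(q_by_coord: dict[str, float], spec: MuscleSpec):
    """(l_mt, {coordinate: moment arm}) at the given coordinate values.

    ``l_mt = l_mt0 - sum_c integral_0^{q_c} arm_c(q) dq`` with per-coordinate
    polynomial arms, so the moment arm is exactly -d(l_mt)/dq.
    """
    l_mt = spec.l_mt0
    arms: dict[str, float] = {}
    for coord, coeffs in spec.moment_arm_coeffs.items():
        if coord not in q_by_coord:
            raise ValueError(f"muscle {spec.name!r} spans unknown coordinate {coord!r}")
        qc = q_by_coord[coord]
        arm = 0.0
        integ = 0.0
        for k, ck in enumerate(coeffs):
            arm = arm + ck * qc**k
            integ = integ + ck * qc ** (k + 1) / (k + 1)
        arms[coord] = arm
        l_mt = l_mt - integ
    return l_mt, arms


def joint_moments_from_muscles(forces: np.ndarray, arms: np.ndarray) -> np.ndarray:
    """Generalized moments = arms^T . forces (arms: n_muscles x n_coords)."""
    forces = np.asarray(forces)
    arms = np.asarray(arms)
    if arms.shape[0] != forces.shape[0]:
        raise ValueError("moment-arm matrix and force vector disagree in muscle count")
    return arms.T @ forces


class MuscleGroup:
    """Vectorized view of a muscle set against a model coordinate layout.

    Evaluations broadcast over a leading batch axis and accept complex input
    (for complex-step Jacobians).
    """

    def __init__(self, specs: list[MuscleSpec], coordinate_names: list[str]):
        self.specs = specs
        self.coordinate_names = list(coordinate_names)
        n_m, n_q = len(specs), len(coordinate_names)
        self.f_max = np.array([m.f_max for m in specs])
        self.l_opt = np.array([m.l_opt for m in specs])
        self.width = np.array([m.width for m in specs])
        self.s_opt = np.array([m.s_opt for m in specs])
        self.l_slack = np.array([m.l_slack for m in specs])
        self.l_mt0 = np.array([m.l_mt0 for m in specs])
        self.tau_act = np.array([m.tau_act for m in specs])
        self.tau_deact = np.array([m.tau_deact for m in specs])
        self.fl_width = np.array([m.fl_width for m in specs])
        self.v_max = np.array([m.v_max for m in specs])
        self.strain_fmax = np.array([m.tendon_strain_at_fmax for m in specs])
        self.damping = np.array([m.damping for m in specs])
        max_deg = 1
        for m in specs:
            for coeffs in m.moment_arm_coeffs.values():
                max_deg = max(max_deg, len(coeffs))
        # poly[k, i, j]: coefficient of q_j^k in muscle i's arm about coord j
        self.poly = np.zeros((max_deg, n_m, n_q))
        for i, m in enumerate(specs):
            for coord, coeffs in m.moment_arm_coeffs.items():
                if coord not in self.coordinate_names:
                    raise ValueError(f"muscle {m.name!r} spans unknown coordinate {coord!r}")
                j = self.coordinate_names.index(coord)
                for k, ck in enumerate(coeffs):
                    self.poly[k, i, j] = ck

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.specs]

    def lengths_and_arms(self, q):
        """q: (..., n_q) -> (l_mt (..., n_m), arms (..., n_m, n_q))."""
        q = np.asarray(q)
        qk = q[..., None, :]                       # (..., 1, n_q)
        arms = np.zeros(q.shape[:-1] + self.poly.shape[1:], dtype=q.dtype)
        integ = np.zeros_like(arms)
        pw = np.ones_like(qk)
        for k in range(self.poly.shape[0]):
            arms = arms + self.poly[k] * pw
            integ = integ + self.poly[k] * pw * qk / (k + 1)
            pw = pw * qk
        l_mt = self.l_mt0 - np.sum(integ, axis=-1)
        return l_mt, arms

    def contraction_residuals(self, s, sdot, a, l_mt):
        lf = np.sqrt(s * s + self.width**2)
        cos_p = s / lf
        lf_dot = s * sdot / lf
        v_norm = lf_dot / (self.l_opt * self.v_max)
        lfn = lf / self.l_opt
        d = (lfn - 1.0) / self.fl_width
        fl = np.exp(-d * d)
        fv = (_FV_D1 * np.arcsinh(_FV_D2 * v_norm + _FV_D3) + _FV_D4) / _FV_NORM
        fpe = passive_force_length(lfn)
        f_fiber = (a * fl * fv + fpe + self.damping * lf_dot / self.l_opt) * self.f_max
        f_t = self._tendon_force(l_mt - s)
        return (f_t - cos_p * f_fiber) / self.f_max, f_t

    def _tendon_force(self, l_tendon):
        eps = l_tendon / self.l_slack - 1.0
        eps_toe = self.strain_fmax / 2.0
        norm = _tendon_raw(self.strain_fmax, eps_toe)
        return self.f_max * _tendon_raw(eps, eps_toe) / norm

    def unit_force_estimate(self, q):
        """Isometric force per unit activation at posture q (rigid tendon).

        Used by controllers to size excitations; not part of the dynamics.
        """
        l_mt, _ = self.lengths_and_arms(np.asarray(q, dtype=float))
        s_rt = np.clip(l_mt - self.l_slack, 0.4 * self.s_opt, 1.6 * self.s_opt)
        lf = np.sqrt(s_rt**2 + self.width**2)
        cos_p = s_rt / lf
        d = (lf / self.l_opt - 1.0) / self.fl_width
        return self.f_max * np.exp(-d * d) * cos_p

    def activation_residuals(self, a, adot, u):
        blend = 0.5 + 0.5 * np.tanh(40.0 * (u - a))
        rate = blend / self.tau_act + (1.0 - blend) * (0.5 + 1.5 * a) / self.tau_deact
        return adot - rate * (u - a)
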