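"""Smooth scalar primitives shared by the dynamics pipeline.

Everything the implicit system residual touches must be continuously
differentiable (the collocation NLP is gradient-based) and analytic in the
complex-step sense: Jacobians are obtained by evaluating the residual at
``x + i*h`` and taking ``imag/h``.  Hence no ``abs``/``max``/``clip`` in this
module — only their smooth regularizations.  Branching, where unavoidable,
is done on the real part so the complex step stays valid away from the
(measure-zero) switch point.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "smooth_abs",
    "smooth_max",
    "smooth_pos",
    "softplus",
    "unit_regularized",
    "complex_step_jacobian",
]


def smooth_abs(x, eps: float = 1e-6):
    """|x| regularized as sqrt(x^2 + eps^2) - eps (zero at zero)."""
    return np.sqrt(x * x + eps * eps) - eps


def smooth_max(a, b, eps: float = 1e-6):
    """max(a, b) with a C^1 blend of half-width ~eps."""
    d = a - b
    return 0.5 * (a + b + np.sqrt(d * d + eps * eps))


def smooth_pos(x, eps: float = 1e-6):
    """max(x, 0) with a C^1 blend; == smooth_max(x, 0)."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def softplus(x, sharpness: float = 1.0):
    """log(1 + exp(k x)) / k, overflow-safe and complex-step safe."""
    z = np.asarray(x * sharpness)
    out = np.where(np.real(z) > 30.0, z, np.log1p(np.exp(np.where(np.real(z) > 30.0, 0.0, z))))
    return out / sharpness


def unit_regularized(v, eps: float = 1e-3):
    """v / ||v|| saturating smoothly to zero as ||v|| -> 0.

    ``v`` has shape (..., d); the norm is taken over the last axis.
    """
    v = np.asarray(v)
    n2 = np.sum(v * v, axis=-1, keepdims=True)
    return v / np.sqrt(n2 + eps * eps)


def complex_step_jacobian(fun, x, h: float = 1e-30):
    """Machine-precision Jacobian of ``fun`` at real vector ``x``.

    ``fun`` must accept complex input and be analytic along the evaluation
    path.  Returns shape (len(fun(x)), len(x)).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.asarray(fun(x))
    jac = np.empty((f0.size, n))
    for j in range(n):
        xp = x.astype(complex)
        xp[j] += 1j * h
        jac[:, j] = np.imag(np.asarray(fun(xp)).ravel()) / h
    return jac
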