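"""Matérn 5/2 covariance kernel and its derivatives.

The surrogate model uses the Matérn 5/2 correlation function

    f(d) = (1 + sqrt(5) d + 5 d^2 / 3) exp(-sqrt(5) d),

with the anisotropic scaled distance d = sqrt(sum_k ((x_k - x'_k)/l_k)^2).
The per-dimension characteristic lengths ``l_k`` are set *noniteratively*
from the eigenvalues of a positive-definite guess Hessian so that a
single-data-point surrogate has predictor curvature ``eps_k`` along
dimension ``k``:

    l_k = sqrt(5 (mu - E_max) / (3 eps_k)).

Gradient-enhanced Kriging needs the kernel value, its first and second
cross-derivatives (to fill the covariance matrix), and — because the inner
microiterations use the surrogate Hessian — third derivatives along the
data-gradient channels.  All derivatives here are closed forms expressed
through three radial factors ``g1, g2, g3`` that stay finite at coincident
points (the Matérn 5/2 kernel is C^4 around d = 0, so every quantity used
here has a well-defined symmetric limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SQRT5 = np.sqrt(5.0)

__all__ = [
    "LengthScales",
    "KernelBlock",
    "scaled_distance",
    "matern52",
    "kernel_block",
    "lengths_from_eigenvalues",
]


@dataclass(frozen=True)
class LengthScales:
    """Per-dimension characteristic lengths of the kernel.

    Parameters
    ----------
    l : (K,) array of positive floats, in units of the reduced coordinate.
    """

    l: np.ndarray

    def __post_init__(self):
        l = np.atleast_1d(np.asarray(self.l, dtype=float))
        if l.ndim != 1:
            raise ValueError("length scales must be a 1-D vector")
        if not np.all(l > 0):
            raise ValueError("all characteristic lengths must be positive")
        object.__setattr__(self, "l", l)

    @property
    def k(self) -> int:
        return self.l.size


@dataclass(frozen=True)
class KernelBlock:
    """Kernel value and derivatives between two points x and x'.

    ``grad_x``/``grad_xp`` are derivatives with respect to x and x',
    ``cross_hessian[k, j] = d^2 f / dx_k dx'_j``.
    """

    value: float
    grad_x: np.ndarray
    grad_xp: np.ndarray
    cross_hessian: np.ndarray


def _check_inputs(x, xp, lengths):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xp = np.atleast_1d(np.asarray(xp, dtype=float))
    if not isinstance(lengths, LengthScales):
        lengths = LengthScales(np.asarray(lengths, dtype=float))
    if x.shape != xp.shape or x.size != lengths.k:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, x' {xp.shape}, l ({lengths.k},)"
        )
    return x, xp, lengths


def scaled_distance(x, xp, lengths) -> float:
    """Anisotropic distance sqrt(sum_k ((x_k - x'_k)/l_k)^2)."""
    x, xp, lengths = _check_inputs(x, xp, lengths)
    s = (x - xp) / lengths.l
    return float(np.sqrt(np.dot(s, s)))


def matern52(d: float) -> float:
    """Matérn 5/2 correlation as a function of the scaled distance."""
    d = float(d)
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return (1.0 + SQRT5 * d + 5.0 * d * d / 3.0) * np.exp(-SQRT5 * d)


def _radial_factors(d: float):
    """Radial factors for derivatives in the scaled coordinate s.

    With F(s) = f(|s|):
        dF/ds_k                   = g1 s_k
        d2F/ds_k ds_j             = g1 δ_kj + g2 s_k s_j
        d3F/ds_i ds_j ds_k        = g2 (δ_ij s_k + δ_ik s_j + δ_jk s_i)
                                    + g3 s_i s_j s_k
    g3 itself diverges like 1/d at the origin but always multiplies three
    powers of s, so the third derivative vanishes there; the caller uses
    the d > 0 branch only when it is safe.
    """
    e = np.exp(-SQRT5 * d)
    g1 = -(5.0 / 3.0) * (1.0 + SQRT5 * d) * e
    g2 = (25.0 / 3.0) * e
    g3 = -(25.0 * SQRT5 / 3.0) * e / d if d > 0 else 0.0
    return g1, g2, g3


def kernel_block(x, xp, lengths) -> KernelBlock:
    """Kernel value plus first and second cross-derivatives.

    All derivatives are exact closed forms; at coincident points the
    symmetric limits apply (gradients vanish, the cross Hessian is
    diag(5 / (3 l_k^2))).
    """
    x, xp, lengths = _check_inputs(x, xp, lengths)
    l = lengths.l
    s = (x - xp) / l
    d = float(np.sqrt(np.dot(s, s)))
    g1, g2, _ = _radial_factors(d)

    value = matern52(d)
    grad_x = g1 * s / l
    # chain rule: d/dx'_k = -(1/l_k) d/ds_k
    grad_xp = -grad_x
    cross = -(np.outer(1.0 / l, 1.0 / l)) * (g1 * np.eye(l.size) + g2 * np.outer(s, s))
    return KernelBlock(value=value, grad_x=grad_x, grad_xp=grad_xp, cross_hessian=cross)


def kernel_derivatives(x, xp, lengths):
    """Full derivative set needed by the surrogate predictor.

    Returns ``(value, grad_x, dxp, hess_xx, cross, third)`` where

    - ``grad_x[k]   = d f / dx_k``
    - ``dxp[k]      = d f / dx'_k``
    - ``hess_xx[kj] = d^2 f / dx_k dx_j``
    - ``cross[kj]   = d^2 f / dx_k dx'_j``
    - ``third[kjm]  = d^3 f / dx_k dx_j dx'_m``

    The third-derivative tensor is what makes the predictor Hessian of a
    gradient-enhanced model available in closed form.
    """
    x, xp, lengths = _check_inputs(x, xp, lengths)
    l = lengths.l
    k = l.size
    s = (x - xp) / l
    d = float(np.sqrt(np.dot(s, s)))
    g1, g2, g3 = _radial_factors(d)

    value = matern52(d)
    eye = np.eye(k)
    grad_s = g1 * s
    hess_s = g1 * eye + g2 * np.outer(s, s)
    # d3F/ds_i ds_j ds_m
    third_s = g2 * (
        eye[:, :, None] * s[None, None, :]
        + eye[:, None, :] * s[None, :, None]
        + eye[None, :, :] * s[:, None, None]
    ) + g3 * s[:, None, None] * s[None, :, None] * s[None, None, :]

    inv_l = 1.0 / l
    grad_x = grad_s * inv_l
    dxp = -grad_x
    hess_xx = hess_s * np.outer(inv_l, inv_l)
    cross = -hess_xx
    third = -third_s * inv_l[:, None, None] * inv_l[None, :, None] * inv_l[None, None, :]
    return value, grad_x, dxp, hess_xx, cross, third


def lengths_from_eigenvalues(eps, mu: float, e_max: float) -> LengthScales:
    """Characteristic lengths reproducing guess-Hessian eigenvalues.

    A single-point surrogate built with these lengths has predictor
    curvature ``eps_k`` along dimension ``k``.  Requires ``mu > e_max``
    (the constant prior mean sits above the highest data energy) and
    strictly positive eigenvalues — callers floor their guess-Hessian
    spectrum first.
    """
    eps = np.atleast_1d(np.asarray(eps, dtype=float))
    if np.any(eps <= 0):
        raise ValueError("Hessian eigenvalues must be positive (floor them first)")
    if not mu > e_max:
        raise ValueError("prior mean mu must exceed the maximum data energy")
    return LengthScales(np.sqrt(5.0 * (mu - e_max) / (3.0 * eps)))
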