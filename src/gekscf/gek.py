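"""Gradient-enhanced Kriging surrogate on the reduced subspace.

The model interpolates energies *and* gradients of up to 20 previous
iterations exactly:

    E*(x) = mu + v(x)^T M^{-1} (y - 1 mu)

where ``M`` is the generalized covariance matrix (kernel values plus all
first and second cross-derivatives between data points), ``v(x)`` the
generalized covariance vector at the prediction point, ``y`` the stacked
energies and gradients, and ``1`` an indicator that is one at energy
positions.  The centered form (subtracting ``1 mu``) is used throughout:
it reproduces the training data exactly and relaxes to the prior mean
``mu`` far from all data.  The predicted variance

    s^2(x) = (y - 1 mu)^T M^{-1} (y - 1 mu) / m * [1 - v^T M^{-1} v]

is what the restricted-variance step control consumes: it is zero at the
data points and grows toward a far-field plateau, so the step length is
limited by model uncertainty rather than by an arbitrary trust radius.

Block layout of ``y`` and ``M`` (fixed for reproducibility): the m
energies first, then the m reduced gradients grouped by data point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .matern import LengthScales, kernel_block, kernel_derivatives

__all__ = [
    "TrainingSet",
    "GekModel",
    "SurrogatePrediction",
    "GekConditioningError",
    "assemble",
    "predict",
    "variance_far_field",
]

#: additive diagonal nugget used when the plain factorization fails
NUGGET = 1e-10
#: variance values above this negative tolerance are clamped to zero
VARIANCE_CLAMP = 1e-10


class GekConditioningError(RuntimeError):
    """Raised when M stays singular after conditioning; callers prune history."""


@dataclass(frozen=True)
class TrainingSet:
    """Reduced-subspace data: m coordinates with energies and gradients."""

    coords: np.ndarray   # (m, K)
    energies: np.ndarray  # (m,)
    grads: np.ndarray    # (m, K)

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        grads = np.atleast_2d(np.asarray(self.grads, dtype=float))
        if coords.shape != grads.shape or coords.shape[0] != energies.size:
            raise ValueError("inconsistent training-set shapes")
        if coords.shape[0] < 1:
            raise ValueError("at least one data point is required")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "energies", energies)
        object.__setattr__(self, "grads", grads)

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class GekModel:
    training: TrainingSet
    mu: float
    lengths: LengthScales
    M: np.ndarray
    y: np.ndarray
    ones_mask: np.ndarray
    alpha: np.ndarray = field(repr=False)        # M^{-1} (y - 1 mu)
    cho: tuple = field(repr=False)               # cho_factor handle for M
    spread: float = 0.0                          # (y-1mu)^T M^{-1} (y-1mu) / m


@dataclass(frozen=True)
class SurrogatePrediction:
    energy: float
    gradient: np.ndarray
    hessian: np.ndarray
    variance: float


def _build_covariance(training: TrainingSet, lengths: LengthScales) -> np.ndarray:
    m, k = training.m, training.k
    n = m * (1 + k)
    big = np.empty((n, n))
    xs = training.coords
    for i in range(m):
        for j in range(m):
            blk = kernel_block(xs[i], xs[j], lengths)
            big[i, j] = blk.value
            # energy(i) vs gradient channels of point j: d f(x_i, x_j)/dx_j
            big[i, m + j * k: m + (j + 1) * k] = blk.grad_xp
            big[m + i * k: m + (i + 1) * k, j] = blk.grad_x
            big[m + i * k: m + (i + 1) * k, m + j * k: m + (j + 1) * k] = (
                blk.cross_hessian
            )
    return big


def assemble(training: TrainingSet, lengths: LengthScales, mu: float) -> GekModel:
    """Build the surrogate from reduced data.

    Conditioning policy: plain Cholesky first; on failure retry once with
    a tiny diagonal nugget; if that also fails the caller is told (via
    :class:`GekConditioningError`) to prune its history and reassemble.
    """
    if lengths.k != training.k:
        raise ValueError("length-scale dimension does not match training data")
    m, k = training.m, training.k
    big = _build_covariance(training, lengths)

    ones_mask = np.zeros(m * (1 + k))
    ones_mask[:m] = 1.0
    y = np.concatenate([training.energies, training.grads.reshape(-1)])
    resid = y - ones_mask * mu

    cho = None
    for nugget in (0.0, NUGGET):
        try:
            cho = scipy.linalg.cho_factor(
                big + nugget * np.eye(big.shape[0]), lower=True
            )
            break
        except scipy.linalg.LinAlgError:
            continue
    if cho is None:
        raise GekConditioningError(
            "generalized covariance matrix is singular; prune history"
        )
    alpha = scipy.linalg.cho_solve(cho, resid)
    spread = float(resid @ alpha) / m
    return GekModel(
        training=training,
        mu=float(mu),
        lengths=lengths,
        M=big,
        y=y,
        ones_mask=ones_mask,
        alpha=alpha,
        cho=cho,
        spread=spread,
    )


def _covariance_vector_and_derivs(model: GekModel, x: np.ndarray):
    """v(x) together with its gradient and Hessian in x."""
    m, k = model.training.m, model.training.k
    n = m * (1 + k)
    v = np.empty(n)
    dv = np.empty((k, n))
    d2v = np.empty((k, k, n))
    for i in range(m):
        value, grad_x, dxp, hess_xx, cross, third = kernel_derivatives(
            x, model.training.coords[i], model.lengths
        )
        v[i] = value
        dv[:, i] = grad_x
        d2v[:, :, i] = hess_xx
        sl = slice(m + i * k, m + (i + 1) * k)
        # gradient channels carry d f / dx'_j; derivatives in x follow.
        v[sl] = dxp
        dv[:, sl] = cross  # d/dx_k (df/dx'_j)
        d2v[:, :, sl] = third
    return v, dv, d2v


def predict(model: GekModel, x) -> SurrogatePrediction:
    """Energy, gradient, Hessian and variance of the surrogate at ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    v, dv, d2v = _covariance_vector_and_derivs(model, x)
    energy = model.mu + float(v @ model.alpha)
    gradient = dv @ model.alpha
    hessian = d2v @ model.alpha
    hessian = 0.5 * (hessian + hessian.T)
    w = scipy.linalg.cho_solve(model.cho, v)
    var = model.spread * (1.0 - float(v @ w))
    if var < 0:
        if var < -max(VARIANCE_CLAMP, 1e-9 * abs(model.spread)):
            # genuine negativity beyond round-off would indicate a bug
            raise FloatingPointError(f"variance {var} below clamp tolerance")
        var = 0.0
    return SurrogatePrediction(
        energy=energy, gradient=gradient, hessian=hessian, variance=var
    )


def variance_far_field(model: GekModel) -> float:
    """Limit of the predicted variance as the covariance vector vanishes."""
    return model.spread
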