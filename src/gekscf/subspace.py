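"""Subspace compression of the orbital-rotation space.

The full optimization space has dimension n = n_occ * n_vir (per spin),
but the surrogate model lives in a subspace of dimension K <= 2m + 2
spanned by the m displacements and m gradients of the stored history,
the current gradient, and one cheap expansion direction (a GDIIS- or
BFGS-predicted displacement; only its direction matters).

The selected vectors are orthonormalized (modified Gram-Schmidt with
re-orthogonalization; near-dependent vectors are dropped), the diagonal
guess Hessian is projected onto the subspace and diagonalized, and the
resulting eigenvector basis P_hat maps coordinates and gradients between
the full space and the subspace:

    x^r = P_hat^T x^f,    g^r = P_hat^T g^f,    dx^f = P_hat dx^r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SubspaceBasis",
    "HistoryRecord",
    "collect_vectors",
    "orthonormalize",
    "project_hessian",
    "project_point",
    "back_transform",
    "diis_direction",
    "bfgs_direction",
]

#: relative drop tolerance for near-dependent vectors
DROP_TOL = 1e-8
#: DIIS extrapolation coefficients beyond this trigger the reset path
DIIS_COEFF_MAX = 15.0


@dataclass(frozen=True)
class HistoryRecord:
    """One stored iteration, expressed in the current reference frame."""

    x_full: np.ndarray
    g_full: np.ndarray
    energy: float


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal subspace with the projected-Hessian eigenbasis.

    ``B`` spans the subspace, ``P_hat = B R`` is the Hessian-eigenvector
    basis used for all projections, ``eps`` its (ascending) eigenvalues.
    """

    B: np.ndarray
    P_hat: np.ndarray
    eps: np.ndarray

    @property
    def k(self) -> int:
        return self.P_hat.shape[1]


def collect_vectors(
    history: Sequence[HistoryRecord],
    g_current: np.ndarray,
    expansion: np.ndarray | None = None,
    x_current: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Candidate spanning vectors, in the fixed insertion order.

    Order (oldest history first): the m displacements x_i - x_current,
    the m gradients, the current gradient, then the expansion direction —
    at most 2m + 2 vectors.  The order matters: it decides which
    near-dependent vectors the orthonormalization drops.
    """
    g_current = np.asarray(g_current, dtype=float)
    x0 = np.zeros_like(g_current) if x_current is None else np.asarray(x_current)
    vecs = [np.asarray(rec.x_full, dtype=float) - x0 for rec in history]
    vecs += [np.asarray(rec.g_full, dtype=float) for rec in history]
    vecs.append(g_current)
    if expansion is not None:
        vecs.append(np.asarray(expansion, dtype=float))
    return vecs


def orthonormalize(vectors: Sequence[np.ndarray], tol: float = DROP_TOL) -> np.ndarray:
    """Modified Gram-Schmidt with one re-orthogonalization pass.

    A vector is dropped when its residual after projection on the columns
    already accepted falls below ``tol`` times its own norm (zero vectors
    are dropped unconditionally).  Returns an n x K matrix, K <= len(vectors).
    """
    cols: list[np.ndarray] = []
    for v in vectors:
        v = np.asarray(v, dtype=float)
        norm0 = np.linalg.norm(v)
        if norm0 <= 0 or not np.isfinite(norm0):
            continue
        w = v.copy()
        for _ in range(2):  # re-orthogonalize for numerical stability
            for c in cols:
                w -= (c @ w) * c
        norm = np.linalg.norm(w)
        if norm < tol * norm0:
            continue
        cols.append(w / norm)
    if not cols:
        raise ValueError("all candidate vectors are below the drop tolerance")
    return np.column_stack(cols)


def project_hessian(B: np.ndarray, h_diag) -> SubspaceBasis:
    """Project a diagonal guess Hessian and diagonalize it.

    ``h_diag`` may be a plain vector (diagonal Hessian) or an operator:
    any callable mapping B to (effective Hessian) @ B — this is how the
    undershoot-mitigation scaling enters without ever forming an n x n
    matrix.
    """
    if callable(h_diag):
        hb = h_diag(B)
    else:
        hb = np.asarray(h_diag, dtype=float)[:, None] * B
    h_r = B.T @ hb
    h_r = 0.5 * (h_r + h_r.T)
    eps, rot = np.linalg.eigh(h_r)
    return SubspaceBasis(B=B, P_hat=B @ rot, eps=eps)


def project_point(P_hat: np.ndarray, v_full) -> np.ndarray:
    """Reduced coordinates/gradient of a full-space vector."""
    return P_hat.T @ np.asarray(v_full, dtype=float)


def back_transform(P_hat: np.ndarray, dx_reduced) -> np.ndarray:
    """Lift a reduced step back into the full space."""
    return P_hat @ np.asarray(dx_reduced, dtype=float)


def _precondition(h_diag: np.ndarray, g: np.ndarray) -> np.ndarray:
    return -g / h_diag


def _solve_diis(errors: list[np.ndarray]) -> np.ndarray | None:
    """DIIS coefficients (sum to one, minimize the combined error norm)."""
    p = len(errors)
    b = np.empty((p + 1, p + 1))
    for i in range(p):
        for j in range(p):
            b[i, j] = errors[i] @ errors[j]
    b[:p, p] = 1.0
    b[p, :p] = 1.0
    b[p, p] = 0.0
    rhs = np.zeros(p + 1)
    rhs[p] = 1.0
    try:
        sol = np.linalg.solve(b, rhs)
    except np.linalg.LinAlgError:
        return None
    c = sol[:p]
    if not np.all(np.isfinite(c)):
        return None
    return c


def diis_extrapolate(
    history: Sequence[HistoryRecord], h_diag: np.ndarray
) -> np.ndarray | None:
    """GDIIS-extrapolated *point* over the stored (x, g) pairs.

    Error vectors are quasi-Newton displacements -diag(h)^{-1} g.  When
    any extrapolation coefficient exceeds ``DIIS_COEFF_MAX`` in absolute
    value the oldest records are discarded and the system re-solved (the
    resetting rule that keeps the extrapolation from diverging).  Returns
    None if no usable extrapolation exists.
    """
    h_diag = np.asarray(h_diag, dtype=float)
    recs = list(history)
    while len(recs) >= 2:
        errors = [_precondition(h_diag, r.g_full) for r in recs]
        c = _solve_diis(errors)
        if c is not None and np.max(np.abs(c)) <= DIIS_COEFF_MAX:
            xs = np.stack([r.x_full for r in recs])
            es = np.stack(errors)
            return c @ xs + c @ es
        recs = recs[1:]
    return None


def diis_direction(history: Sequence[HistoryRecord], h_diag) -> np.ndarray:
    """Unit-norm r-GDIIS-like displacement direction.

    Falls back to the preconditioned steepest-descent direction of the
    newest record whenever the DIIS system is singular or degenerate.
    """
    h_diag = np.asarray(h_diag, dtype=float)
    current = history[-1]
    target = diis_extrapolate(history, h_diag)
    if target is not None:
        step = target - current.x_full
        norm = np.linalg.norm(step)
        if norm > 1e-14:
            return step / norm
    step = _precondition(h_diag, current.g_full)
    norm = np.linalg.norm(step)
    if norm == 0:
        return step
    return step / norm


def bfgs_direction(history: Sequence[HistoryRecord], h_diag) -> np.ndarray:
    """Unit-norm quasi-Newton direction -H_BFGS^{-1} g_current.

    H starts from the diagonal guess and absorbs one BFGS update per
    consecutive history pair; updates violating the curvature condition
    s^T y > 1e-12 |s||y| are skipped so H stays positive definite.
    """
    h_diag = np.asarray(h_diag, dtype=float)
    hmat = np.diag(h_diag)
    for prev, nxt in zip(history[:-1], history[1:]):
        s = nxt.x_full - prev.x_full
        yv = nxt.g_full - prev.g_full
        sty = s @ yv
        if sty <= 1e-12 * np.linalg.norm(s) * np.linalg.norm(yv):
            continue
        hs = hmat @ s
        hmat = hmat + np.outer(yv, yv) / sty - np.outer(hs, hs) / (s @ hs)
    g = history[-1].g_full
    step = -np.linalg.solve(hmat, g)
    norm = np.linalg.norm(step)
    if norm == 0:
        return step
    return step / norm
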