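"""Exponential parametrization of orbital rotations.

Orbital sets are points on a quotient manifold: C' = C exp(kappa) with

    kappa = [[0, X], [-X^T, 0]],

where X (n_occ x n_vir) holds the nonredundant occupied-virtual rotation
parameters.  Because the surrogate model mixes data from several SCF
iterations, all stored coordinates and gradients must refer to *one*
reference orbital set — the current one.  Whenever the reference moves by
a step Delta-kappa, every stored point is rebased:

* coordinates via an SVD retraction: the occupied-occupied block of
  exp(-Delta kappa) exp(kappa) is decomposed as K_oo = V Sigma W^T and
  the new nonredundant block is X~ = -V scos(Sigma) W^T K_vo^T, with
  scos(x) = arccos(x)/sqrt(1 - x^2).  The by-product orthogonal factors
  (U_occ, U_vir) track the redundant occupied/virtual rotations that keep
  the orbital span (and hence the energy) unchanged;

* gradients via the derivative of the exponential map, either as a
  nested-commutator series restricted to the occupied-virtual block, or
  as a noniterative closed form built from the SVD of the evaluation
  coordinate (both are implemented and agree to machine precision — the
  series doubles as an internal cross-check of the closed form).

Flattening between X matrices and coordinate vectors is row-major over
the occupied index, fixed project-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "RebaseError",
    "RebaseResult",
    "expm_blocked",
    "rotate_orbitals",
    "rebase_coordinates",
    "scos",
    "transport_gradient_series",
    "transport_gradient_closed",
    "commutator_series_oracle",
    "occupied_space_overlap",
    "embed_antisymmetric",
]


class RebaseError(RuntimeError):
    """Occupied-space rotation too large to rebase (vanishing singular value)."""


@dataclass(frozen=True)
class RebaseResult:
    """New coordinates plus the redundant-rotation factors of a rebase."""

    x_tilde: np.ndarray
    u_occ: np.ndarray
    u_vir: np.ndarray


def embed_antisymmetric(x: np.ndarray) -> np.ndarray:
    """Full antisymmetric generator [[0, X], [-X^T, 0]]."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    no, nv = x.shape
    kappa = np.zeros((no + nv, no + nv))
    kappa[:no, no:] = x
    kappa[no:, :no] = -x.T
    return kappa


def expm_blocked(x: np.ndarray) -> np.ndarray:
    """exp of the blocked antisymmetric generator, via the SVD closed form.

    With X = U Sigma V^T:

        exp(kappa) = [[I + U(cos S - I)U^T,  U sin S V^T],
                      [-V sin S U^T,         I + V(cos S - I)V^T]]

    which is exactly orthogonal by construction (no series truncation).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    no, nv = x.shape
    u, sig, vt = np.linalg.svd(x, full_matrices=False)
    v = vt.T
    cos_m1 = np.cos(sig) - 1.0
    sin_s = np.sin(sig)
    out = np.eye(no + nv)
    out[:no, :no] += (u * cos_m1) @ u.T
    out[:no, no:] = (u * sin_s) @ v.T
    out[no:, :no] = -(v * sin_s) @ u.T
    out[no:, no:] += (v * cos_m1) @ v.T
    return out


def rotate_orbitals(c: np.ndarray, s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """C' = C exp(kappa); preserves S-orthonormality of the coefficients."""
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    ortho = c.T @ s @ c
    if not np.allclose(ortho, np.eye(c.shape[1]), atol=1e-10):
        raise ValueError("input orbitals are not S-orthonormal")
    return c @ expm_blocked(x)


def scos(x) -> np.ndarray:
    """arccos(x)/sqrt(1 - x^2), continuous with scos(1) = 1.

    Near x = 1 the direct quotient is 0/0; there the equivalent form
    t / sin(t) with t = arccos(x) is evaluated by its Taylor series,
    which is accurate to machine precision for t < 1e-2.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("scos argument outside [-1, 1]")
    xc = np.clip(x, -1.0, 1.0)
    t = np.arccos(xc)
    small = t < 1e-2
    out = np.empty_like(t)
    ts = t[small]
    t2 = ts * ts
    # t/sin t = 1 + t^2/6 + 7 t^4/360 + 31 t^6/15120 + ...
    out[small] = 1.0 + t2 / 6.0 + 7.0 * t2 * t2 / 360.0 + 31.0 * t2 ** 3 / 15120.0
    tb = t[~small]
    out[~small] = tb / np.sin(tb)
    return out if out.ndim else float(out)


def rebase_coordinates(x: np.ndarray, dx: np.ndarray) -> RebaseResult:
    """Coordinates of the point exp(kappa(x)) relative to the new reference
    C exp(kappa(dx)).

    Fails (``RebaseError``) when a singular value of the occupied-occupied
    block vanishes, i.e. the combined rotation turns an occupied orbital by
    90 degrees — the caller is expected to restart its history instead.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dx = np.atleast_2d(np.asarray(dx, dtype=float))
    no, nv = x.shape
    k = expm_blocked(-dx) @ expm_blocked(x)
    k_oo = k[:no, :no]
    k_vo = k[no:, :no]
    k_ov = k[:no, no:]
    k_vv = k[no:, no:]
    v, sig, wt = np.linalg.svd(k_oo)
    if sig.min() < 1e-8:
        raise RebaseError(
            "vanishing singular value in occupied-occupied overlap; "
            "rotation too large to rebase"
        )
    w = wt.T
    x_tilde = -(v * scos(sig)) @ w.T @ k_vo.T
    # The redundant-rotation factors are fixed by the defining relation
    #   C_tilde exp(kappa_tilde) = C exp(kappa) blockdiag(U_occ, U_vir);
    # the transpose convention below is the one that satisfies it exactly
    # (verified against K^T exp(kappa_tilde), which is block diagonal).
    u_occ = w @ v.T
    u_vir = (k_vv - k_vo @ w @ np.diag(1.0 / (sig + 1.0)) @ v.T @ k_ov).T
    return RebaseResult(x_tilde=x_tilde, u_occ=u_occ, u_vir=u_vir)


#: series guard: abort if the nested series has not converged by this order
SERIES_MAX_TERMS = 40


def transport_gradient_series(
    l_block: np.ndarray,
    dx: np.ndarray,
    u_occ: np.ndarray,
    u_vir: np.ndarray,
) -> np.ndarray:
    """Gradient transport by the even nested-commutator series.

    T_0 = U_occ^T L U_vir, then with P = X X^T (X the evaluation
    coordinate block; only even powers of X enter, so its overall sign is
    immaterial):

        T_k = (2 X T_{k-1}^T - T_{k-1} X^T) X - P T_{k-1}
        L~  = sum_k T_k / (2k + 1)!

    Terms are summed until max|T_k|/(2k+1)! drops below machine precision.
    """
    x = np.atleast_2d(np.asarray(dx, dtype=float))
    t = np.asarray(u_occ).T @ np.atleast_2d(np.asarray(l_block, dtype=float)) @ u_vir
    p = x @ x.T
    total = t.copy()
    scale0 = max(np.max(np.abs(t)), 1.0)
    for k in range(1, SERIES_MAX_TERMS + 1):
        t = (2.0 * x @ t.T - t @ x.T) @ x - p @ t
        term = t / factorial(2 * k + 1)
        total += term
        if np.max(np.abs(term)) < np.finfo(float).eps * scale0:
            return total
    raise RuntimeError(
        "gradient-transport series did not converge; rotation step too large"
    )


def transport_gradient_closed(
    l_block: np.ndarray,
    dx: np.ndarray,
    u_occ: np.ndarray,
    u_vir: np.ndarray,
) -> np.ndarray:
    """Noniterative gradient transport from the SVD of the coordinate block.

    With X = R Gamma Q^T, Z = R^T T_0 Q and the singularity-free sinc
    combinations D^±_ij = sinc(gamma_i ± gamma_j)/2:

        L~ = R[(Z + Z^T) ⊙ D^- + (Z - Z^T) ⊙ D^+] Q^T
             + (R sinc(Gamma) R^T) T_0 (I - Q Q^T)

    Requires n_vir >= n_occ (the thin-SVD convention behind the final
    projector term); this is the usual situation for SCF problems.
    """
    x = np.atleast_2d(np.asarray(dx, dtype=float))
    no, nv = x.shape
    if nv < no:
        raise ValueError("closed-form transport assumes n_vir >= n_occ")
    t0 = np.asarray(u_occ).T @ np.atleast_2d(np.asarray(l_block, dtype=float)) @ u_vir
    r, gam, qt = np.linalg.svd(x, full_matrices=False)
    q = qt.T
    z = r.T @ t0 @ q
    d_minus = np.sinc((gam[:, None] - gam[None, :]) / np.pi) / 2.0
    d_plus = np.sinc((gam[:, None] + gam[None, :]) / np.pi) / 2.0
    core = (z + z.T) * d_minus + (z - z.T) * d_plus
    out = r @ core @ q.T
    out += (r * np.sinc(gam / np.pi)) @ r.T @ t0 @ (np.eye(nv) - q @ q.T)
    return out


def commutator_series_oracle(
    g_full: np.ndarray, nu_full: np.ndarray, terms: int
) -> np.ndarray:
    """Brute-force truncation of the derivative-of-exp series.

    G~(nu) = sum_k ad_nu^k(G(0)) / (k+1)!  — used only as a test oracle
    for the blocked transport formulas.
    """
    g = np.asarray(g_full, dtype=float)
    nu = np.asarray(nu_full, dtype=float)
    term = g.copy()
    total = np.zeros_like(g)
    for k in range(terms + 1):
        total += term / factorial(k + 1)
        term = nu @ term - term @ nu
    return total


def occupied_space_overlap(c1: np.ndarray, c2: np.ndarray, s: np.ndarray) -> float:
    """Product of the singular values of C1_occ^T S C2_occ.

    Equals 1 iff the two occupied sets span the same space; 0 if any
    dimension of one set is S-orthogonal to the other.  Callers pass the
    occupied blocks only.
    """
    m = np.asarray(c1).T @ np.asarray(s) @ np.asarray(c2)
    sv = np.linalg.svd(m, compute_uv=False)
    return float(np.prod(np.clip(sv, 0.0, 1.0 + 1e-12)))
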