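"""Toy restricted/unrestricted Hartree-Fock objective backends.

The optimization variables are the occupied-virtual orbital-rotation
parameters X (per spin for UHF); the energy and Fock matrix are rebuilt
from scratch at every reference change, and the orbital gradient is the
occupied-virtual block of the MO-basis Fock matrix times a constant that
is pinned by finite differences (-4 for a restricted determinant, -2 per
spin for an unrestricted one; the factor two between them is the double
occupancy of restricted spatial orbitals).

History rebasing composes the SVD coordinate retraction with the
closed-form gradient transport: each record keeps, besides its frame
coordinates and gradient, the gradient at its *own* orbitals aligned by
the accumulated redundant-rotation factors; the frame gradient is the
even nested-commutator transport of that payload evaluated at the
record's current coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .. import kappa
from .base import ObjectiveBackend
from .integrals import Integrals, build_integrals

__all__ = ["HFState", "HFBackend", "build_toy_system", "energy_and_fock",
           "gradient_block"]


@dataclass
class HFState:
    """Current SCF reference: AO integrals plus per-spin MO coefficients."""

    integrals: Integrals
    c: tuple[np.ndarray, ...]       # per-spin AO x MO coefficients
    n_occ: tuple[int, ...]          # per-spin occupation counts
    restricted: bool
    energy: float = 0.0
    f_mo: tuple[np.ndarray, ...] = ()

    @property
    def s(self) -> np.ndarray:
        return self.integrals.s

    @property
    def h_core(self) -> np.ndarray:
        return self.integrals.h_core

    @property
    def eri(self) -> np.ndarray:
        return self.integrals.eri


def _fock_matrices(ints: Integrals, dens: list[np.ndarray], restricted: bool):
    eri = ints.eri
    if restricted:
        d = dens[0]
        j = np.einsum("mnls,ls->mn", eri, d)
        k = np.einsum("mlns,ls->mn", eri, d)
        f = ints.h_core + j - 0.5 * k
        e_el = 0.5 * float(np.sum(d * (ints.h_core + f)))
        return [f], e_el
    d_tot = dens[0] + dens[1]
    j = np.einsum("mnls,ls->mn", eri, d_tot)
    focks, e_el = [], 0.0
    for d in dens:
        k = np.einsum("mlns,ls->mn", eri, d)
        f = ints.h_core + j - k
        focks.append(f)
        e_el += 0.5 * float(np.sum(d * (ints.h_core + f)))
    return focks, e_el


def energy_and_fock(state: HFState, c: tuple[np.ndarray, ...] | None = None):
    """Total energy and per-spin MO-basis Fock matrices for coefficients c.

    The energy depends only on the occupied spans, so it is invariant
    under occupied-occupied (and virtual-virtual) rotations of c.
    """
    ints = state.integrals
    cs = state.c if c is None else c
    if state.restricted:
        co = cs[0][:, : state.n_occ[0]]
        dens = [2.0 * co @ co.T]
    else:
        dens = [cm[:, :no] @ cm[:, :no].T for cm, no in zip(cs, state.n_occ)]
    focks, e_el = _fock_matrices(ints, dens, state.restricted)
    f_mo = tuple(cm.T @ f @ cm for cm, f in zip(cs, focks))
    return e_el + ints.e_nuc, f_mo


def gradient_block(state: HFState, f_mo: tuple[np.ndarray, ...]):
    """Occupied-virtual gradient blocks dE/dX_ia at the reference.

    Only valid at the reference orbitals: after any rotation the Fock
    matrix must be rebuilt before calling this again.
    """
    pref = -4.0 if state.restricted else -2.0
    out = []
    for f, no in zip(f_mo, state.n_occ):
        out.append(pref * f[:no, no:])
    return out


def build_toy_system(
    xyz: str, basis: str = "sto-3g", charge: int = 0, multiplicity: int = 1
) -> "HFBackend":
    """Core-guess HF backend for an H/He system described in XYZ text."""
    ints = build_integrals(xyz, basis=basis, charge=charge)
    n_el = ints.n_electrons
    n_unpaired = multiplicity - 1
    if (n_el - n_unpaired) % 2 or n_unpaired < 0 or n_unpaired > n_el:
        raise ValueError(
            f"charge/multiplicity ({charge}/{multiplicity}) inconsistent "
            f"with {n_el} electrons"
        )
    n_beta = (n_el - n_unpaired) // 2
    n_alpha = n_beta + n_unpaired
    restricted = multiplicity == 1
    # core guess: diagonalize h in the S-orthonormal metric
    _, c0 = scipy.linalg.eigh(ints.h_core, ints.s)
    if restricted:
        cs, nocc = (c0.copy(),), (n_alpha,)
    else:
        cs, nocc = (c0.copy(), c0.copy()), (n_alpha, n_beta)
    state = HFState(integrals=ints, c=cs, n_occ=nocc, restricted=restricted)
    return HFBackend(state)


class HFBackend(ObjectiveBackend):
    """Hartree-Fock objective over orbital-rotation coordinates."""

    def __init__(self, state: HFState):
        self.state = state
        nbf = state.integrals.nbf
        self.shapes = [(no, nbf - no) for no in state.n_occ]
        if any(nv < no for no, nv in self.shapes):
            raise ValueError("backend assumes n_vir >= n_occ per spin")
        self.n = sum(no * nv for no, nv in self.shapes)
        self._refresh()

    # -- coordinate flattening ------------------------------------------
    def split(self, flat: np.ndarray) -> list[np.ndarray]:
        out, k = [], 0
        for no, nv in self.shapes:
            out.append(np.asarray(flat[k: k + no * nv]).reshape(no, nv))
            k += no * nv
        return out

    def flatten(self, blocks) -> np.ndarray:
        return np.concatenate([np.asarray(b).reshape(-1) for b in blocks])

    # -- backend contract -----------------------------------------------
    def _refresh(self):
        e, f_mo = energy_and_fock(self.state)
        self.state.energy = e
        self.state.f_mo = f_mo
        self._grad = self.flatten(gradient_block(self.state, f_mo))

    def evaluate(self):
        return self.state.energy, self._grad.copy()

    def apply_step(self, dx):
        blocks = self.split(np.asarray(dx, dtype=float))
        new_c = tuple(
            kappa.rotate_orbitals(cm, self.state.s, x)
            for cm, x in zip(self.state.c, blocks)
        )
        self.state.c = new_c
        self._refresh()

    def make_aux(self, g):
        # gradient at the record's own orbitals; at creation the record *is*
        # the reference, so the payload equals the frame gradient blocks.
        return [b.copy() for b in self.split(np.asarray(g, dtype=float))]

    def rebase_record(self, x, g, aux, dx):
        xs = self.split(np.asarray(x, dtype=float))
        dxs = self.split(np.asarray(dx, dtype=float))
        new_x, new_g, new_aux = [], [], []
        for xb, dxb, l0 in zip(xs, dxs, aux):
            rb = kappa.rebase_coordinates(xb, dxb)
            l0p = rb.u_occ.T @ l0 @ rb.u_vir
            gb = kappa.transport_gradient_closed(
                l0p, rb.x_tilde, np.eye(xb.shape[0]), np.eye(xb.shape[1])
            )
            new_x.append(rb.x_tilde)
            new_g.append(gb)
            new_aux.append(l0p)
        return self.flatten(new_x), self.flatten(new_g), new_aux

    def hessian_guess(self):
        # orbital-energy differences, scaled consistently with the
        # finite-difference-pinned gradient prefactor
        pref = 4.0 if self.state.restricted else 2.0
        out = []
        for f, (no, nv) in zip(self.state.f_mo, self.shapes):
            eps = np.diag(f)
            out.append(pref * (eps[no:][None, :] - eps[:no][:, None]))
        return self.flatten(out)

    def conv_gradient(self) -> float:
        return max(
            float(np.max(np.abs(f[:no, no:])))
            for f, (no, nv) in zip(self.state.f_mo, self.shapes)
        )

    def occupied_coefficients(self) -> list[np.ndarray]:
        return [cm[:, :no] for cm, no in zip(self.state.c, self.state.n_occ)]

    def overlap_with(self, other: "HFBackend") -> float:
        """Product of per-spin occupied-space overlaps with another backend."""
        out = 1.0
        for c1, c2 in zip(self.occupied_coefficients(),
                          other.occupied_coefficients()):
            out *= kappa.occupied_space_overlap(c1, c2, self.state.s)
        return out
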