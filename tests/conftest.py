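"""Shared fixtures: toy geometries and independent oracles."""

import numpy as np
import pytest

H2_XYZ = "2\nh2\nH 0 0 0\nH 0.74 0 0\n"
HEHP_XYZ = "2\nhehp\nHe 0 0 0\nH 0.93 0 0\n"
H3_XYZ = "3\nh3 chain\nH 0 0 0\nH 0.9 0 0\nH 1.8 0 0\n"
H4_XYZ = "4\nh4 chain\nH 0 0 0\nH 1.0 0 0\nH 2.0 0 0\nH 3.0 0 0\n"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_hf_energy(backend) -> float:
    """Determinant expectation value by explicit spin-orbital loops.

    Independent of the Fock-matrix route: transforms integrals with
    einsum contractions over explicit occupied spin-orbital pairs and
    sums one-electron, Coulomb and (same-spin) exchange terms directly.
    """
    st = backend.state
    ints = st.integrals
    occ, spins = [], []
    if st.restricted:
        for i in range(st.n_occ[0]):
            for s in (0, 1):
                occ.append((st.c[0], i))
                spins.append(s)
    else:
        for sp, (cm, no) in enumerate(zip(st.c, st.n_occ)):
            for i in range(no):
                occ.append((cm, i))
                spins.append(sp)
    h = ints.h_core
    eri = ints.eri
    energy = ints.e_nuc
    for cm, i in occ:
        ci = cm[:, i]
        energy += ci @ h @ ci
    for a, ((ca, i), sa) in enumerate(zip(occ, spins)):
        for b, ((cb, j), sb) in enumerate(zip(occ, spins)):
            if a == b:
                continue
            ci, cj = ca[:, i], cb[:, j]
            coul = np.einsum("m,n,l,s,mnls->", ci, ci, cj, cj, eri)
            exch = (
                np.einsum("m,n,l,s,mnls->", ci, cj, cj, ci, eri)
                if sa == sb
                else 0.0
            )
            energy += 0.5 * (coul - exch)
    return float(energy)


def finite_difference_gradient(fun, x, h=1e-6):
    """Central-difference gradient of a scalar function of a vector."""
    x = np.asarray(x, dtype=float)
    grad = np.zeros_like(x)
    for k in range(x.size):
        dp = np.zeros_like(x)
        dp[k] = h
        grad[k] = (fun(x + dp) - fun(x - dp)) / (2 * h)
    return grad
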