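"""One- and two-electron integrals over s-type Gaussian basis functions.

Only H and He are supported, with contracted s functions: closed-form
overlap, kinetic, nuclear-attraction and repulsion integrals through the
zeroth-order Boys function.  This keeps the engine tiny while producing
genuine SCF energy surfaces (restricted and unrestricted) on which the
orbital optimizers are exercised.

Geometries come in standard XYZ (count line, comment, element x y z in
Ångström); all integrals are in atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "Shell",
    "Integrals",
    "BASIS_SETS",
    "parse_xyz",
    "build_integrals",
    "h_chain_xyz",
]

ANGSTROM_TO_BOHR = 1.8897259886
NUCLEAR_CHARGE = {"H": 1.0, "HE": 2.0}

# Exponents/contraction coefficients for s-only sets.  Coefficients refer
# to normalized primitives; contracted functions are renormalized below.
BASIS_SETS: dict[str, dict[str, list[tuple[list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [([3.42525091, 0.62391373, 0.16885540],
               [0.15432897, 0.53532814, 0.44463454])],
        "HE": [([6.36242139, 1.15892300, 0.31364979],
                [0.15432897, 0.53532814, 0.44463454])],
    },
    "6-31g": {
        "H": [([18.73113696, 2.825394365, 0.640121692],
               [0.03349460, 0.23472695, 0.81375733]),
              ([0.161277759], [1.0])],
        "HE": [([38.421634, 5.77803, 1.241774],
                [0.04013974, 0.26124610, 0.79318462]),
               ([0.297964], [1.0])],
    },
}


@dataclass(frozen=True)
class Shell:
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray  # include primitive norms and contraction normalization


@dataclass(frozen=True)
class Integrals:
    s: np.ndarray
    t: np.ndarray
    v: np.ndarray
    eri: np.ndarray
    e_nuc: float
    n_electrons: int

    @property
    def h_core(self) -> np.ndarray:
        return self.t + self.v

    @property
    def nbf(self) -> int:
        return self.s.shape[0]


def parse_xyz(text: str) -> list[tuple[str, np.ndarray]]:
    """Parse XYZ text; coordinates converted from Ångström to bohr."""
    lines = [ln for ln in text.strip().splitlines()]
    natoms = int(lines[0].split()[0])
    atoms = []
    for ln in lines[2: 2 + natoms]:
        parts = ln.split()
        sym = parts[0].upper()
        xyz = np.array([float(p) for p in parts[1:4]]) * ANGSTROM_TO_BOHR
        atoms.append((sym, xyz))
    if len(atoms) != natoms:
        raise ValueError("XYZ atom count does not match header")
    return atoms


def h_chain_xyz(n: int, bond: float = 1.0, jitter: float = 0.0, seed: int = 0) -> str:
    """Linear H-chain geometry in XYZ format (bond length in Ångström)."""
    rng = np.random.default_rng(seed)
    lines = [str(n), f"H{n} chain, r={bond} A"]
    for i in range(n):
        dx = rng.normal(scale=jitter) if jitter else 0.0
        lines.append(f"H {i * bond + dx:.10f} 0.0 0.0")
    return "\n".join(lines) + "\n"


def _boys0(t: np.ndarray) -> np.ndarray:
    """F_0(t) = (1/2) sqrt(pi/t) erf(sqrt t), with the small-t series."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    small = t < 1e-12
    out[small] = 1.0 - t[small] / 3.0
    tb = t[~small]
    out[~small] = 0.5 * np.sqrt(np.pi / tb) * erf(np.sqrt(tb))
    return out


def _make_shells(atoms, basis: str) -> list[Shell]:
    try:
        table = BASIS_SETS[basis]
    except KeyError:
        raise ValueError(f"unknown basis set {basis!r}") from None
    shells = []
    for sym, xyz in atoms:
        if sym not in NUCLEAR_CHARGE:
            raise ValueError(f"unsupported element {sym!r}: only H and He")
        for exps, coefs in table[sym]:
            exps = np.asarray(exps, dtype=float)
            coefs = np.asarray(coefs, dtype=float) * (2.0 * exps / np.pi) ** 0.75
            shells.append(Shell(center=np.asarray(xyz, float), exps=exps, coefs=coefs))
    # renormalize each contracted function so the overlap diagonal is 1
    out = []
    for sh in shells:
        ss = 0.0
        for a, ca in zip(sh.exps, sh.coefs):
            for b, cb in zip(sh.exps, sh.coefs):
                ss += ca * cb * (np.pi / (a + b)) ** 1.5
        out.append(Shell(sh.center, sh.exps, sh.coefs / np.sqrt(ss)))
    return out


def build_integrals(
    atoms_or_xyz, basis: str = "sto-3g", charge: int = 0
) -> Integrals:
    """All AO integrals for a geometry (list of atoms or XYZ text)."""
    atoms = parse_xyz(atoms_or_xyz) if isinstance(atoms_or_xyz, str) else atoms_or_xyz
    shells = _make_shells(atoms, basis)
    nbf = len(shells)
    if nbf > 10:
        raise ValueError("toy integral engine is limited to 10 basis functions")

    s = np.zeros((nbf, nbf))
    t = np.zeros((nbf, nbf))
    v = np.zeros((nbf, nbf))
    centers = [(NUCLEAR_CHARGE[sym], xyz) for sym, xyz in atoms]
    for i, si in enumerate(shells):
        for j, sj in enumerate(shells):
            rab2 = float(np.sum((si.center - sj.center) ** 2))
            for a, ca in zip(si.exps, si.coefs):
                for b, cb in zip(sj.exps, sj.coefs):
                    p = a + b
                    mu = a * b / p
                    pref = ca * cb * np.exp(-mu * rab2)
                    sab = pref * (np.pi / p) ** 1.5
                    s[i, j] += sab
                    t[i, j] += mu * (3.0 - 2.0 * mu * rab2) * sab
                    pc = (a * si.center + b * sj.center) / p
                    for z, rc in centers:
                        tt = p * float(np.sum((pc - rc) ** 2))
                        v[i, j] -= z * pref * (2.0 * np.pi / p) * _boys0(
                            np.array([tt])
                        )[0]

    eri = np.zeros((nbf, nbf, nbf, nbf))
    for i, si in enumerate(shells):
        for j, sj in enumerate(shells):
            if j > i:
                continue
            rab2 = float(np.sum((si.center - sj.center) ** 2))
            for k, sk in enumerate(shells):
                for l, sl in enumerate(shells):
                    if l > k or (k, l) > (i, j):
                        continue
                    rcd2 = float(np.sum((sk.center - sl.center) ** 2))
                    val = 0.0
                    for a, ca in zip(si.exps, si.coefs):
                        for b, cb in zip(sj.exps, sj.coefs):
                            p = a + b
                            pc = (a * si.center + b * sj.center) / p
                            ea = np.exp(-a * b / p * rab2)
                            for c, cc in zip(sk.exps, sk.coefs):
                                for d, cd in zip(sl.exps, sl.coefs):
                                    q = c + d
                                    qc = (c * sk.center + d * sl.center) / q
                                    eb = np.exp(-c * d / q * rcd2)
                                    tt = (
                                        p * q / (p + q)
                                        * float(np.sum((pc - qc) ** 2))
                                    )
                                    val += (
                                        ca * cb * cc * cd * ea * eb
                                        * 2.0 * np.pi ** 2.5
                                        / (p * q * np.sqrt(p + q))
                                        * _boys0(np.array([tt]))[0]
                                    )
                    for (ii, jj) in ((i, j), (j, i)):
                        for (kk, ll) in ((k, l), (l, k)):
                            eri[ii, jj, kk, ll] = val
                            eri[kk, ll, ii, jj] = val

    e_nuc = 0.0
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            za, ra = centers[a]
            zb, rb = centers[b]
            e_nuc += za * zb / np.linalg.norm(ra - rb)

    n_el = int(round(sum(z for z, _ in centers))) - charge
    ev = np.linalg.eigvalsh(s)
    if ev.min() < 1e-10:
        raise ValueError("linear dependence in basis (overlap eigenvalue < 1e-10)")
    return Integrals(s=s, t=t, v=v, eri=eri, e_nuc=e_nuc, n_electrons=n_el)
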