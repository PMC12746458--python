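"""Outer optimization loops: S-GEK/RVO and the r-GDIIS baseline.

One S-GEK/RVO iteration:

1. evaluate energy/gradient at the current reference and append the
   point to the history (at most 20 records, oldest dropped);
2. span a subspace with the stored displacements and gradients, the
   current gradient, and one cheap expansion direction (GDIIS- or
   BFGS-predicted displacement);
3. project the (possibly loosened) diagonal guess Hessian, set the
   kernel characteristic lengths from its eigenvalues, and assemble the
   gradient-enhanced Kriging surrogate from the projected history;
4. run restricted-step rational-function (RS-RFO) microiterations on the
   surrogate until a stationary point is found or the predicted variance
   hits the limit (proportional to the reduced gradient norm);
5. back-transform the step, rotate the orbitals, rebase every stored
   record to the new reference, and update the loosening factor by
   comparing consecutive step directions.

The r-GDIIS baseline shares the history/rebase plumbing and replaces
steps 2-4 with a quasi-Newton-preconditioned GDIIS extrapolation with a
coefficient-reset rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import gek, subspace
from .backends.base import ObjectiveBackend
from .kappa import RebaseError
from .matern import lengths_from_eigenvalues

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "RunResult",
    "optimize",
    "rgdiis_optimize",
    "variance_limit",
    "update_loosening",
    "scale_hessian",
    "rsrfo_microiterations",
    "converged",
    "guess_hessian",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

METHODS = ("rgdiis", "sgek-diis", "sgek-bfgs")


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunable parameters of the optimizers (defaults are the working set).

    Tolerances mirror standard SCF practice: simultaneous energy change
    below ``e_tol``, max occupied-virtual Fock element below ``fock_tol``
    and step norm below ``step_tol`` (all strict inequalities).
    """

    max_history: int = 20
    expansion_method: str = "diis"          # diis | bfgs | none
    variance_coefficient: float = 0.3       # var_max = c * |g_reduced|
    mu_offset: float = 10.0                 # hartree above the max data energy
    loosen_factor: float = GOLDEN_RATIO
    tighten_angle: float = 20.0             # degrees; reset f_L above this
    loosen_angle: float = 5.0               # degrees; multiply f_L below this
    e_tol: float = 1e-9
    fock_tol: float = 1.5e-4
    step_tol: float = 1e-3
    max_iter: int = 400
    hessian_floor: float = 0.025
    seed: int = 0
    mitigation: bool = True
    first_step_norm: float = 0.3            # cap on the initial descent step
    rgdiis_step_norm: float = 0.5           # cap on baseline extrapolation steps
    micro_max: int = 200

    def __post_init__(self):
        if self.loosen_angle >= self.tighten_angle:
            raise ValueError("loosen_angle must be below tighten_angle")
        for name in ("e_tol", "fock_tol", "step_tol", "variance_coefficient",
                     "hessian_floor", "mu_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class _Record:
    x: np.ndarray
    g: np.ndarray
    energy: float
    aux: object = None

    def public(self) -> subspace.HistoryRecord:
        return subspace.HistoryRecord(self.x, self.g, self.energy)


@dataclass
class OptimizerState:
    history: list = field(default_factory=list)
    f_l: float = 1.0
    prev_step: np.ndarray | None = None
    iteration: int = 0
    trace: list = field(default_factory=list)


@dataclass
class RunResult:
    method: str
    converged: bool
    iterations: int
    final_energy: float
    trace: pd.DataFrame
    state: OptimizerState
    backend: ObjectiveBackend


def guess_hessian(backend: ObjectiveBackend, cfg: OptimizerConfig) -> np.ndarray:
    """Floored positive diagonal guess Hessian from the backend."""
    return np.maximum(backend.hessian_guess(), cfg.hessian_floor)


def variance_limit(g_reduced: np.ndarray, cfg: OptimizerConfig) -> float:
    """Maximum allowed surrogate variance: proportional to the gradient."""
    return cfg.variance_coefficient * float(np.linalg.norm(g_reduced))


def update_loosening(
    state: OptimizerState, new_step: np.ndarray, cfg: OptimizerConfig
) -> float:
    """Next loosening factor from the angle between consecutive steps.

    Near-parallel steps (angle below ``loosen_angle``) are the signature
    of systematic undershooting on a flat slope: the factor grows by the
    golden ratio so the next surrogate is built with softer curvature
    along that direction.  A direction change beyond ``tighten_angle``
    resets the factor to one; in between it is left alone.
    """
    if state.prev_step is None or not cfg.mitigation:
        return state.f_l
    a, b = np.asarray(state.prev_step), np.asarray(new_step)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return state.f_l
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    angle = math.degrees(math.acos(cosang))
    if angle < cfg.loosen_angle:
        return state.f_l * cfg.loosen_factor
    if angle > cfg.tighten_angle:
        return 1.0
    return state.f_l


def scale_hessian(h_diag: np.ndarray, f_l: float, q_dir: np.ndarray):
    """Operator form of the loosened Hessian H~ = W^T H W.

    W = I + (1/f_L - 1) q q^T softens the curvature along the repeated
    step direction q by 1/f_L^2 and leaves orthogonal directions alone.
    Returned as a callable B -> H~ B so the n x n matrix is never formed.
    """
    h_diag = np.asarray(h_diag, dtype=float)
    q = np.asarray(q_dir, dtype=float)
    q = q / np.linalg.norm(q)
    c = 1.0 / f_l - 1.0

    def apply(b: np.ndarray) -> np.ndarray:
        wb = b + np.outer(q, c * (q @ b))
        hwb = h_diag[:, None] * wb
        return hwb + np.outer(q, c * (q @ hwb))

    return apply


def _rfo_step(hess: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Rational-function step from the augmented-Hessian eigenproblem."""
    k = grad.size
    aug = np.empty((k + 1, k + 1))
    aug[:k, :k] = hess
    aug[:k, k] = grad
    aug[k, :k] = grad
    aug[k, k] = 0.0
    evals, evecs = np.linalg.eigh(aug)
    v = evecs[:, 0]
    if abs(v[k]) < 1e-12:
        # degenerate augmented problem: fall back to a shifted Newton step
        shift = min(0.0, float(np.linalg.eigvalsh(hess)[0])) - 1e-8
        return -np.linalg.solve(hess - shift * np.eye(k), grad)
    return v[:k] / v[k]


def rsrfo_microiterations(
    model: gek.GekModel,
    x0: np.ndarray,
    var_max: float,
    cfg: OptimizerConfig,
) -> tuple[np.ndarray, str, float]:
    """Walk the surrogate to a stationary point under the variance wall.

    Returns ``(step, stop_reason, variance_at_endpoint)``.  The variance
    restriction is enforced by bisection on the final segment (at most 30
    bisections, tolerance 1e-6 on the variance), so when the wall is hit
    the returned endpoint sits on it.
    """
    x0 = np.asarray(x0, dtype=float)
    if var_max <= 0.0:
        return np.zeros_like(x0), "variance_truncated", 0.0
    x = x0.copy()
    trust = 0.5 * float(np.min(model.lengths.l))
    trust_max = 10.0 * trust
    pred = gek.predict(model, x)
    for _ in range(cfg.micro_max):
        if np.linalg.norm(pred.gradient) < 1e-8:
            return x - x0, "stationary", pred.variance
        step = _rfo_step(pred.hessian, pred.gradient)
        norm = np.linalg.norm(step)
        if norm > trust:
            step = step * (trust / norm)
        xn = x + step
        pn = gek.predict(model, xn)
        if pn.variance > var_max:
            lo, hi = 0.0, 1.0
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                pm = gek.predict(model, x + mid * step)
                if abs(pm.variance - var_max) <= 1e-6 * max(1.0, var_max):
                    break
                if pm.variance > var_max:
                    hi = mid
                else:
                    lo = mid
            else:
                mid = lo
                pm = gek.predict(model, x + mid * step)
            return (x + mid * step) - x0, "variance_truncated", pm.variance
        if pn.energy > pred.energy + 1e-14:
            trust *= 0.5
            if trust < 1e-12:
                return x - x0, "trust_collapse", pred.variance
            continue
        x, pred = xn, pn
        trust = min(trust * 1.2, trust_max)
    return x - x0, "micro_limit", pred.variance


def _first_step(g: np.ndarray, h_diag: np.ndarray, cap: float) -> np.ndarray:
    step = -g / h_diag
    norm = np.linalg.norm(step)
    if norm > cap:
        step *= cap / norm
    return step


def _propose_sgek(
    state: OptimizerState,
    backend: ObjectiveBackend,
    cfg: OptimizerConfig,
) -> tuple[np.ndarray, dict]:
    """One surrogate step from the current history (current point last)."""
    current = state.history[-1]
    g = current.g
    h_diag = guess_hessian(backend, cfg)
    if len(state.history) == 1:
        return _first_step(g, h_diag, cfg.first_step_norm), {
            "variance": 0.0, "K": 0, "stop": "first"}

    public = [r.public() for r in state.history]
    if cfg.expansion_method == "diis":
        expansion = subspace.diis_direction(public, h_diag)
    elif cfg.expansion_method == "bfgs":
        expansion = subspace.bfgs_direction(public, h_diag)
    elif cfg.expansion_method == "none":
        expansion = None
    else:
        raise ValueError(f"unknown expansion method {cfg.expansion_method!r}")

    vectors = subspace.collect_vectors(public[:-1], g, expansion)
    b = subspace.orthonormalize(vectors)

    if cfg.mitigation and state.f_l > 1.0 and state.prev_step is not None:
        h_op = scale_hessian(h_diag, state.f_l, state.prev_step)
    else:
        h_op = h_diag
    basis = subspace.project_hessian(b, h_op)
    eps = np.maximum(basis.eps, cfg.hessian_floor)

    records = list(state.history)
    while True:
        coords = np.stack([subspace.project_point(basis.P_hat, r.x)
                           for r in records])
        grads = np.stack([subspace.project_point(basis.P_hat, r.g)
                          for r in records])
        energies = np.array([r.energy for r in records])
        e_max = float(energies.max())
        mu = e_max + cfg.mu_offset
        lengths = lengths_from_eigenvalues(eps, mu, e_max)
        try:
            model = gek.assemble(
                gek.TrainingSet(coords, energies, grads), lengths, mu
            )
            break
        except gek.GekConditioningError:
            if len(records) <= 1:
                raise
            records = records[1:]  # drop the oldest, reassemble

    x0 = subspace.project_point(basis.P_hat, current.x)
    g_r = subspace.project_point(basis.P_hat, g)
    var_max = variance_limit(g_r, cfg)
    dxr, stop, var = rsrfo_microiterations(model, x0, var_max, cfg)
    dx = subspace.back_transform(basis.P_hat, dxr)
    return dx, {"variance": var, "K": basis.k, "stop": stop, "basis": basis}


def _propose_rgdiis(
    state: OptimizerState, backend: ObjectiveBackend, cfg: OptimizerConfig
) -> tuple[np.ndarray, dict]:
    current = state.history[-1]
    h_diag = guess_hessian(backend, cfg)
    info = {"variance": float("nan"), "K": 0, "stop": "diis"}
    if len(state.history) == 1:
        return _first_step(current.g, h_diag, cfg.first_step_norm), info
    target = subspace.diis_extrapolate([r.public() for r in state.history],
                                       h_diag)
    if target is None:
        return _first_step(current.g, h_diag, cfg.first_step_norm), info
    step = target - current.x
    norm = np.linalg.norm(step)
    if norm > cfg.rgdiis_step_norm:
        step *= cfg.rgdiis_step_norm / norm
    return step, info


def converged(
    d_energy: float | None,
    grad_max: float,
    step_norm: float | None,
    cfg: OptimizerConfig,
) -> bool:
    """Simultaneous, strict test of the three convergence criteria."""
    if d_energy is None or step_norm is None:
        return False
    return (
        abs(d_energy) < cfg.e_tol
        and grad_max < cfg.fock_tol
        and step_norm < cfg.step_tol
    )


def optimize(
    backend: ObjectiveBackend,
    method: str = "sgek-diis",
    cfg: OptimizerConfig | None = None,
) -> RunResult:
    """Run one optimizer on one backend until convergence or ``max_iter``.

    ``method`` is one of ``rgdiis`` (baseline), ``sgek-diis`` or
    ``sgek-bfgs`` (surrogate optimizer with the corresponding subspace
    expansion).  Nonconvergence is a reported status, not an exception.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    cfg = cfg or OptimizerConfig()
    if method == "sgek-bfgs":
        cfg = replace(cfg, expansion_method="bfgs")
    state = OptimizerState()
    prev_energy: float | None = None
    last_step_norm: float | None = None
    is_converged = False

    for it in range(cfg.max_iter):
        state.iteration = it
        energy, grad = backend.evaluate()
        grad_max = backend.conv_gradient()
        state.history.append(
            _Record(x=np.zeros(backend.n), g=grad, energy=energy,
                    aux=backend.make_aux(grad))
        )
        if len(state.history) > cfg.max_history:
            state.history = state.history[-cfg.max_history:]

        d_energy = None if prev_energy is None else energy - prev_energy
        if converged(d_energy, grad_max, last_step_norm, cfg):
            is_converged = True
            state.trace.append({
                "iter": it, "energy": energy, "d_energy": d_energy,
                "g_max": grad_max, "step_norm": 0.0, "variance": 0.0,
                "f_L": state.f_l, "K": 0, "method": method,
            })
            break

        if method == "rgdiis":
            step, info = _propose_rgdiis(state, backend, cfg)
        else:
            step, info = _propose_sgek(state, backend, cfg)

        step_norm = float(np.linalg.norm(step))
        state.trace.append({
            "iter": it, "energy": energy, "d_energy": d_energy,
            "g_max": grad_max, "step_norm": step_norm,
            "variance": info["variance"], "f_L": state.f_l,
            "K": info["K"], "method": method,
        })

        backend.apply_step(step)
        try:
            for rec in state.history:
                rec.x, rec.g, rec.aux = backend.rebase_record(
                    rec.x, rec.g, rec.aux, step
                )
        except RebaseError:
            state.history = []  # rotation too large: restart the history

        state.f_l = update_loosening(state, step, cfg)
        state.prev_step = step
        prev_energy = energy
        last_step_norm = step_norm

    trace = pd.DataFrame(state.trace)
    return RunResult(
        method=method,
        converged=is_converged,
        iterations=len(trace),
        final_energy=float(backend.evaluate()[0]),
        trace=trace,
        state=state,
        backend=backend,
    )


def rgdiis_optimize(
    backend: ObjectiveBackend, cfg: OptimizerConfig | None = None
) -> RunResult:
    """Baseline r-GDIIS optimization (shared outer loop)."""
    return optimize(backend, method="rgdiis", cfg=cfg)
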