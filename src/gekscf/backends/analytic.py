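"""Analytic objective surfaces.

These share the backend contract with the SCF problems but live in a
flat space: displacements are vector additions and history rebasing is a
translation of coordinates (gradients are frame-independent).

Surfaces:

``quadratic``
    E = 1/2 (x - x0)^T A (x - x0) with SPD A — convexity/exactness checks.
``slope``
    A tilted plane with constant downhill gradient that turns into a
    quadratic bowl only beyond a distant floor.  In the flat sloped
    region a variance-restricted surrogate systematically undershoots,
    which is exactly the regime the loosening heuristic targets.
``flat_valley``
    Strongly anisotropic quadratic (one near-zero curvature).
``rosenbrock``
    The classic banana valley (gradient-consistency fixture).
"""

from __future__ import annotations

import numpy as np

from .base import ObjectiveBackend

__all__ = ["AnalyticBackend", "analytic_surface", "SURFACES"]


class AnalyticBackend(ObjectiveBackend):
    def __init__(self, fun, x0, curvature_scale: float = 1.0, name: str = ""):
        self.fun = fun
        self.x = np.asarray(x0, dtype=float).copy()
        self.n = self.x.size
        self.curvature_scale = float(curvature_scale)
        self.name = name

    def evaluate(self):
        e, g = self.fun(self.x)
        return float(e), np.asarray(g, dtype=float)

    def apply_step(self, dx):
        self.x = self.x + np.asarray(dx, dtype=float)

    def rebase_record(self, x, g, aux, dx):
        return np.asarray(x) - np.asarray(dx), np.asarray(g), aux

    def hessian_guess(self):
        return np.full(self.n, self.curvature_scale)


def _quadratic(params):
    if "a" not in params:  # default bowl for command-line demos
        params = {**params, "a": np.diag([2.0, 1.0, 0.5]),
                  "center": np.array([1.0, -1.0, 0.5])}
    a = np.asarray(params["a"], dtype=float)
    center = np.asarray(params.get("center", np.zeros(a.shape[0])), dtype=float)

    def fun(x):
        d = x - center
        return 0.5 * d @ a @ d, a @ d

    return fun, params.get("x0", np.zeros(a.shape[0])), float(np.mean(np.diag(a)))


def _slope(params):
    slope = float(params.get("slope", 1.0))
    floor = float(params.get("floor", 1e3))
    curv = float(params.get("curvature", 1.0))

    def fun(x):
        x0 = float(x[0])
        excess = max(0.0, x0 - floor)
        e = -slope * x0 + 0.5 * curv * excess * excess
        g = np.array([-slope + curv * excess])
        return e, g

    return fun, params.get("x0", np.zeros(1)), float(params.get("guess", 1.0))


def _flat_valley(params):
    n = int(params.get("n", 2))
    curvs = np.asarray(params.get("curvatures", [1e-3] + [1.0] * (n - 1)), float)

    def fun(x):
        return 0.5 * float(np.sum(curvs * x * x)), curvs * x

    return fun, params.get("x0", np.ones(n)), float(np.mean(curvs))


def _rosenbrock(params):
    def fun(x):
        a, b = 1.0, 100.0
        e = (a - x[0]) ** 2 + b * (x[1] - x[0] ** 2) ** 2
        g = np.array([
            -2 * (a - x[0]) - 4 * b * x[0] * (x[1] - x[0] ** 2),
            2 * b * (x[1] - x[0] ** 2),
        ])
        return float(e), g

    return fun, params.get("x0", np.array([-1.2, 1.0])), 50.0


SURFACES = {
    "quadratic": _quadratic,
    "slope": _slope,
    "flat_valley": _flat_valley,
    "rosenbrock": _rosenbrock,
}


def analytic_surface(name: str, params: dict | None = None) -> AnalyticBackend:
    """Construct a named analytic backend."""
    try:
        builder = SURFACES[name]
    except KeyError:
        raise ValueError(
            f"unknown surface {name!r}; choose from {sorted(SURFACES)}"
        ) from None
    fun, x0, scale = builder(params or {})
    return AnalyticBackend(fun, x0, curvature_scale=scale, name=name)
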