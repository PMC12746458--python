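"""Objective-backend contract consumed by the optimizers.

A backend owns a *reference state* (for SCF problems, the current set of
molecular orbitals; for analytic surfaces, a point in R^n) and exposes
the energy and gradient at that reference, a way to displace it, and —
because stored history must stay consistent with the moving reference —
a per-record rebase operation.

The coordinate vector is the flattened nonredundant rotation block
(row-major over the occupied index; for unrestricted problems the alpha
block precedes the beta block).  Analytic backends use ordinary vector
addition, and their rebase is a plain translation.
"""

from __future__ import annotations

import abc

import numpy as np

__all__ = ["ObjectiveBackend"]


class ObjectiveBackend(abc.ABC):
    """Energy/gradient provider with a movable reference state."""

    #: number of optimization parameters
    n: int

    @abc.abstractmethod
    def evaluate(self) -> tuple[float, np.ndarray]:
        """Energy and gradient at the current reference (coordinates = 0)."""

    @abc.abstractmethod
    def apply_step(self, dx: np.ndarray) -> None:
        """Move the reference by the displacement ``dx`` (flattened)."""

    @abc.abstractmethod
    def rebase_record(
        self, x: np.ndarray, g: np.ndarray, aux, dx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, object]:
        """Re-express a stored (coordinates, gradient, payload) triple
        relative to the reference displaced by ``dx``.

        May raise :class:`gekscf.kappa.RebaseError` when the displacement
        is too large to rebase; the driver then restarts its history.
        """

    def make_aux(self, g: np.ndarray):
        """Backend-specific payload stored with a fresh history record."""
        return None

    @abc.abstractmethod
    def hessian_guess(self) -> np.ndarray:
        """Positive diagonal guess Hessian (flattened, same layout as x)."""

    def conv_gradient(self) -> float:
        """Quantity tested against the gradient convergence threshold.

        SCF backends report max |F_ov| (the occupied-virtual Fock element);
        analytic backends fall back to the max absolute gradient entry.
        """
        return float(np.max(np.abs(self.evaluate()[1])))
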