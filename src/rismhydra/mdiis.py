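"""MDIIS (modified direct inversion in the iterative subspace) accelerator.

Picard iteration of the coupled OZ/closure equations converges slowly (or
not at all) for strongly associating solvents.  MDIIS keeps the last few
(solution, residual) pairs and extrapolates the next trial solution as the
residual-norm-minimising linear combination of the stored ones, subject to
the coefficients summing to one, plus a damped step along the combined
residual.  The same accelerator serves both the radial (1D) and the
Cartesian (3D) solvers; solutions are handled as flat vectors.

The scheme degrades gracefully: with ``n_vectors=1`` it reduces to plain
damped Picard mixing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Mdiis"]


class Mdiis:
    """Residual-subspace extrapolation state.

    Parameters
    ----------
    n_vectors:
        Maximum subspace size (the number of stored iterates).
    damping:
        Step size along the extrapolated residual, in (0, 1].
    restart_factor:
        If the current residual norm exceeds ``restart_factor`` times the
        best norm seen, the subspace is reset to the best stored iterate.
    """

    def __init__(self, n_vectors: int = 5, damping: float = 0.7,
                 restart_factor: float = 10.0):
        if n_vectors < 1:
            raise ValueError("n_vectors must be >= 1")
        if not 0.0 < damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")
        self.n_vectors = int(n_vectors)
        self.damping = float(damping)
        self.restart_factor = float(restart_factor)
        self._solutions: list[np.ndarray] = []
        self._residuals: list[np.ndarray] = []
        self._best_norm = np.inf
        self._best_solution: np.ndarray | None = None
        self.n_restarts = 0

    def step(self, x: np.ndarray, residual: np.ndarray) -> np.ndarray:
        """Return the next trial solution given ``x`` and its residual."""
        x = np.asarray(x, dtype=float).ravel()
        residual = np.asarray(residual, dtype=float).ravel()
        norm = float(np.max(np.abs(residual)))

        if norm < self._best_norm:
            self._best_norm = norm
            self._best_solution = x.copy()
        elif norm > self.restart_factor * self._best_norm and len(self._solutions) > 1:
            # The subspace has gone sour: restart from the best point seen.
            self._solutions.clear()
            self._residuals.clear()
            self.n_restarts += 1
            x = self._best_solution.copy()
            # a fresh damped step will be taken from the stored best

        self._solutions.append(x.copy())
        self._residuals.append(residual.copy())
        if len(self._solutions) > self.n_vectors:
            self._solutions.pop(0)
            self._residuals.pop(0)

        m = len(self._solutions)
        if m == 1:
            return x + self.damping * residual

        # Minimise |sum a_i r_i|^2 subject to sum a_i = 1 (Lagrange system).
        R = np.stack(self._residuals)          # (m, n)
        B = R @ R.T
        scale = np.max(np.abs(B))
        if scale > 0:
            B = B / scale
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = B
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        rhs = np.zeros(m + 1)
        rhs[m] = 1.0
        try:
            coeff = np.linalg.solve(A, rhs)[:m]
        except np.linalg.LinAlgError:
            coeff, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            coeff = coeff[:m]

        X = np.stack(self._solutions)
        x_star = coeff @ X
        r_star = coeff @ R
        return x_star + self.damping * r_star
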