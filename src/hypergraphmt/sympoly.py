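"""Elementary-symmetric-polynomial accumulators over the latent hyperedge space.

The EM updates need sums over Omega, the set of *all* potential hyperedges of
sizes 2..D — combinatorially many.  Because the model is assortative, every
such sum factorizes per community k into elementary symmetric polynomials of
the membership column u_.k:

    C_k(d) = sum over d-subsets S of nodes of  prod_{j in S} u_jk

which the standard one-node-at-a-time recurrence builds in O(N D K).  The sum
over hyperedges *containing* a node i uses the leave-one-out polynomial
C_k^(-i), obtained from C_k by deflation in O(D) without touching the other
N-1 nodes:

    C_k^(-i)(d) = C_k(d) - u_ik * C_k^(-i)(d-1),  C_k^(-i)(0) = 1

and after a membership entry changes, folding the node back in restores the
full polynomial at the same cost.  Deflation subtracts nearly-equal numbers
when u_ik dominates its column; tiny negative residues (> -1e-12) are clipped
to zero and anything worse signals the caller to rebuild from scratch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SymPolyCache", "build_esp"]

_CLIP = -1e-12


def build_esp(u: np.ndarray, D: int) -> np.ndarray:
    """Elementary symmetric polynomials of each column of ``u`` up to order D.

    Parameters
    ----------
    u : (N, K) nonnegative array
    D : highest order to compute

    Returns
    -------
    (K, D+1) array C with C[k, d] = e_d(u[:, k]); C[k, 0] = 1.
    """
    N, K = u.shape
    C = np.zeros((K, D + 1))
    C[:, 0] = 1.0
    for j in range(N):
        top = min(D, j + 1)
        for d in range(top, 0, -1):
            C[:, d] += u[j] * C[:, d - 1]
    return C


class SymPolyCache:
    """Per-community ESP accumulators with leave-one-out deflation.

    Attributes
    ----------
    C : (K, D+1) array
        ``C[k, d]`` is the order-d elementary symmetric polynomial of u[:, k].
    """

    def __init__(self, u: np.ndarray, D: int):
        self.D = int(D)
        self.u = u
        self.C = build_esp(u, self.D)

    def rebuild(self) -> None:
        self.C = build_esp(self.u, self.D)

    def deflate(self, i: int) -> np.ndarray:
        """Leave-one-out polynomials C^(-i), shape (K, D+1).

        Raises
        ------
        FloatingPointError
            if cancellation produces a residue below the clipping tolerance;
            callers should rebuild the cache and retry.
        """
        K = self.C.shape[0]
        Cm = np.empty_like(self.C)
        Cm[:, 0] = 1.0
        ui = self.u[i]
        for d in range(1, self.D + 1):
            v = self.C[:, d] - ui * Cm[:, d - 1]
            bad = v < _CLIP
            if np.any(bad):
                raise FloatingPointError("catastrophic cancellation in ESP deflation")
            Cm[:, d] = np.where(v < 0.0, 0.0, v)
        return Cm

    def refold(self, i: int, new_row: np.ndarray, Cm: np.ndarray | None = None) -> None:
        """Set ``u[i] = new_row`` and restore the full polynomials from C^(-i)."""
        if Cm is None:
            Cm = self.deflate(i)
        self.u[i] = new_row
        for d in range(self.D, 0, -1):
            self.C[:, d] = Cm[:, d] + new_row * Cm[:, d - 1]
        self.C[:, 0] = 1.0
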