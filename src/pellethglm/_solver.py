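"""Block-Schur linear algebra for the augmented h-likelihood system.

The augmented (joint) information matrix of the spatial binomial HGLM is

    A = [[ B'WB + P_B,  B'W     ],
         [ WB,          W + Q   ]]

where B collects the dense border columns (fixed effects, plus optional
extra random-effect dummies such as year), W the diagonal GLM weights and
Q the CAR precision.  Under the default neighborhood rule Q -- and hence
M = W + Q -- is block-diagonal across survey years, so A is factorized as
per-year sparse LU factors of M plus a small dense Schur complement for
the border.  This keeps every fit linear in the number of plot-years.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


def spd_logdet_from_lu(lu) -> float:
    """log-determinant from a no-pivot SuperLU factorization of an SPD matrix."""
    du = lu.U.diagonal()
    if np.any(du <= 0):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return float(np.sum(np.log(du)))


def factorize_spd(A: sp.spmatrix):
    """SuperLU with no row pivoting; valid (and fastest) for SPD matrices."""
    return splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                options={"SymmetricMode": True})


class BlockSchurSystem:
    """Factorization of the augmented system for one (W, Q, P_B) setting.

    Parameters
    ----------
    B : (n, p_b) dense border design (fixed effects + extra RE dummies).
    w : (n,) positive GLM weights.
    Q : (n, n) sparse SPD precision of the CAR effects.
    P_B : (p_b, p_b) border prior precision (zeros for fixed effects).
    blocks : list of index arrays partitioning the n units such that Q is
        block-diagonal over them (year blocks; a single block is fine).
    """

    def __init__(self, B, w, Q, P_B, blocks):
        self.B = B
        self.w = np.asarray(w)
        self.Q = Q
        self.blocks = blocks
        self.n, self.pb = B.shape
        M = (sp.diags(self.w) + Q).tocsc()
        self._lus = []
        self._logdetM = 0.0
        for idx in blocks:
            lu = factorize_spd(M[np.ix_(idx, idx)])
            self._lus.append(lu)
            self._logdetM += spd_logdet_from_lu(lu)
        WB = B * self.w[:, None]
        self.Y = self.solve_M(WB)  # M^{-1} W B, (n, p_b)
        S = B.T @ WB + P_B - WB.T @ self.Y
        S = 0.5 * (S + S.T)
        sign, self._logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("Schur complement not positive definite")
        self.S = S
        self.S_inv = np.linalg.inv(S)
        self.WB = WB

    def solve_M(self, R):
        """Solve (W + Q) X = R blockwise; R is (n,) or (n, k)."""
        R = np.asarray(R, dtype=float)
        out = np.empty_like(R, dtype=float)
        for idx, lu in zip(self.blocks, self._lus):
            out[idx] = lu.solve(np.ascontiguousarray(R[idx]))
        return out

    @property
    def logdet(self) -> float:
        return self._logdetM + self._logdetS

    def solve(self, r_b, r_u):
        """Solve A [b; u] = [r_b; r_u]."""
        v = self.solve_M(r_u)
        b = self.S_inv @ (r_b - self.WB.T @ v)
        u = v - self.Y @ b
        return b, u

    def border_cov(self) -> np.ndarray:
        """(A^{-1}) border block = S^{-1}."""
        return self.S_inv

    def trace_uu_times(self, C: sp.spmatrix) -> float:
        """trace((A^{-1})_{uu} C) for sparse symmetric C sharing Q's blocks.

        Uses (A^{-1})_{uu} = M^{-1} + Y S^{-1} Y'.
        """
        tr = 0.0
        Ccsc = C.tocsc()
        for idx, lu in zip(self.blocks, self._lus):
            Cb = Ccsc[np.ix_(idx, idx)]
            if Cb.nnz == 0:
                continue
            dense = np.asarray(Cb.todense())
            tr += float(np.trace(lu.solve(dense)))
        YC = C @ self.Y
        tr += float(np.sum(self.S_inv * (self.Y.T @ YC)))
        return tr
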