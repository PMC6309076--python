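"""Symmetric vectorization: the duplication map Gamma.

A symmetric p-by-p matrix Delta has p(p+1)/2 free parameters theta,
indexed by upper-triangle pairs (j <= k).  Gamma is the p^2-by-p(p+1)/2
0/1 matrix with Gamma[jk, jk] = Gamma[kj, jk] = 1 so that
vec(Delta) = Gamma @ theta.  It is never materialized; this class
provides the three products the solver needs as index operations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SymmetricVectorizer"]


class SymmetricVectorizer:
    """Index bookkeeping between symmetric matrices and theta vectors."""

    def __init__(self, p: int):
        if p < 1:
            raise ValueError("p must be positive")
        self.p = p
        self.rows, self.cols = np.triu_indices(p)
        self.dim = self.rows.size  # p(p+1)/2
        self.is_diag = self.rows == self.cols

    def to_vector(self, matrix: np.ndarray) -> np.ndarray:
        """theta from a symmetric matrix (upper triangle incl. diagonal)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.p, self.p):
            raise ValueError(f"expected ({self.p}, {self.p}) matrix")
        return matrix[self.rows, self.cols].copy()

    def to_matrix(self, theta: np.ndarray) -> np.ndarray:
        """The symmetric matrix form of theta (exactly symmetric)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            raise ValueError(f"expected theta of length {self.dim}")
        m = np.zeros((self.p, self.p))
        m[self.rows, self.cols] = theta
        m[self.cols, self.rows] = theta
        return m

    def gamma_t(self, matrix: np.ndarray) -> np.ndarray:
        """Gamma^T vec(W) for an arbitrary (not necessarily symmetric) W:
        coordinate (j, k), j < k, receives W[j,k] + W[k,j]; coordinate
        (j, j) receives W[j,j]."""
        matrix = np.asarray(matrix, dtype=float)
        s = matrix + matrix.T
        out = s[self.rows, self.cols]
        out[self.is_diag] *= 0.5
        return out
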