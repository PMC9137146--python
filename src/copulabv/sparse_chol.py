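"""Sparse LDL' factorisation with a reusable symbolic analysis.

REML maximisation refactors the mixed-model coefficient matrix at every
likelihood evaluation while its sparsity pattern stays fixed.  General sparse
LU routines redo the fill-reducing ordering and symbolic analysis on each
call, which dominates the cost at animal-model sizes.  This module separates
the two phases for symmetric positive-definite systems: :class:`PatternLDL`
performs ordering (borrowed from SuperLU's minimum-degree ordering of
A + A') and elimination-tree analysis once per pattern, after which each
``factor`` call runs only the numeric up-looking LDL' recurrence (Davis's
LDL algorithm) compiled with numba.

The factor gives ``log|C|`` as ``sum(log d_i)`` and triangular solves for
the mixed-model solutions.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = ["PatternLDL", "LDLFactor"]


@njit(cache=True)
def _symbolic(n, Ap, Ai):
    """Elimination tree and column counts of L for upper-triangular CSC A."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                flag[i] = k
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + lnz[k]
    return parent, Lp


@njit(cache=True)
def _numeric(n, Ap, Ai, Ax, parent, Lp, Li, Lx, D):
    """Up-looking numeric LDL'; returns the index of a non-positive pivot
    (failure) or -1 on success."""
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            m = 0
            while flag[i] != k:
                stack[m] = i
                m += 1
                flag[i] = k
                i = parent[i]
            while m > 0:
                m -= 1
                top -= 1
                pattern[top] = stack[m]
        D[k] = Y[k]
        Y[k] = 0.0
        for s in range(top, n):
            i = pattern[s]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[p2] = k
            Lx[p2] = l_ki
            lnz[i] += 1
        if D[k] <= 0.0:
            return k
    return -1


@njit(cache=True)
def _solve(n, Lp, Li, Lx, D, b):
    """Solve L D L' x = b in place (unit lower-triangular L in CSC)."""
    for j in range(n):
        bj = b[j]
        for p in range(Lp[j], Lp[j + 1]):
            b[Li[p]] -= Lx[p] * bj
    for j in range(n):
        b[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = b[j]
        for p in range(Lp[j], Lp[j + 1]):
            s -= Lx[p] * b[Li[p]]
        b[j] = s
    return b


class LDLFactor:
    """Numeric LDL' factor of a permuted symmetric matrix."""

    def __init__(self, owner: "PatternLDL", Lx: np.ndarray, D: np.ndarray):
        self._o = owner
        self._Lx = Lx
        self._D = D

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        o = self._o
        x = np.ascontiguousarray(b[o.perm], dtype=float)
        _solve(o.n, o._Lp, o._Li, self._Lx, self._D, x)
        out = np.empty_like(x)
        out[o.perm] = x
        return out


class PatternLDL:
    """One-off symbolic analysis of a fixed symmetric sparsity pattern.

    Parameters
    ----------
    pattern : square CSC matrix whose sparsity pattern (both triangles)
        every subsequently factored matrix shares.  Its data values are used
        only to seed the fill-reducing ordering.

    ``factor(data)`` accepts the data array of a CSC matrix with exactly
    this pattern and returns an :class:`LDLFactor`.
    """

    def __init__(self, pattern: sparse.csc_matrix, seed_data: np.ndarray):
        pattern = pattern.tocsc()
        pattern.sort_indices()
        n = pattern.shape[0]
        self.n = n
        seed = sparse.csc_matrix(
            (np.asarray(seed_data, float), pattern.indices, pattern.indptr),
            shape=pattern.shape)
        lu = splu(seed, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                  options=dict(SymmetricMode=True))
        self.perm = np.argsort(np.asarray(lu.perm_c, dtype=np.int64))
        inv = np.empty(n, dtype=np.int64)
        inv[self.perm] = np.arange(n)

        # Map the full-pattern data array onto the upper triangle of the
        # permuted matrix (CSC order), so each factor() call is one gather.
        coo = pattern.tocoo()
        pr = inv[coo.row]
        pc = inv[coo.col]
        keep = pr <= pc
        rows = pr[keep]
        cols = pc[keep]
        src = np.nonzero(keep)[0]
        order = np.lexsort((rows, cols))
        self._gather = src[order]
        Ai = rows[order]
        Ap = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(cols, minlength=n), out=Ap[1:])
        self._Ap = Ap
        self._Ai = np.ascontiguousarray(Ai)
        parent, Lp = _symbolic(n, Ap, self._Ai)
        self._parent = parent
        self._Lp = Lp
        self._Li = np.empty(Lp[n], dtype=np.int64)
        self.fill_nnz = int(Lp[n])

    def factor(self, data: np.ndarray) -> LDLFactor:
        Ax = np.ascontiguousarray(data[self._gather], dtype=float)
        Lx = np.empty(self._Lp[self.n])
        D = np.empty(self.n)
        bad = _numeric(self.n, self._Ap, self._Ai, Ax,
                       self._parent, self._Lp, self._Li, Lx, D)
        if bad >= 0:
            raise np.linalg.LinAlgError(
                f"matrix is not positive definite (pivot {bad})")
        return LDLFactor(self, Lx, D)
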