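"""Sparse LDL' factorization with a Takahashi selected inverse.

EM-REML on Henderson's mixed-model equations needs (i) the solution of
the system, (ii) log|M|, and (iii) *selected* entries of M^-1: the
prediction-error (co)variance blocks that enter the trace terms of the
EM updates, and record-level quadratic forms for the residual update.
All requested entries lie on the nonzero pattern of M itself, which is a
subset of the filled pattern of the Cholesky factor, so the Takahashi
equations deliver them exactly at roughly the cost of the factorization
— no full inverse is ever formed.

The factorization is the up-looking LDL' of Davis (no pivoting; the MME
coefficient matrix is positive definite once the variance-component
priors are added).  A fill-reducing permutation is chosen up front by
comparing symbolic fill under reverse-Cuthill-McKee and natural order.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import reverse_cuthill_mckee
from scipy.sparse.linalg import splu


def fill_reducing_permutation(m: sparse.spmatrix) -> np.ndarray:
    """Symmetric fill-reducing ordering via SuperLU's minimum-degree on
    A'+A (symmetric mode, diagonal pivoting); falls back to
    reverse-Cuthill-McKee if the numeric LU probe fails."""
    try:
        lu = splu(sparse.csc_matrix(m), permc_spec="MMD_AT_PLUS_A",
                  diag_pivot_thresh=0.0, options=dict(SymmetricMode=True))
        return np.argsort(np.asarray(lu.perm_c)).astype(np.int64)
    except Exception:
        return np.asarray(reverse_cuthill_mckee(sparse.csc_matrix(m),
                                                symmetric_mode=True), dtype=np.int64)


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Elimination tree + column counts for upper-triangular CSC A."""
    parent = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
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
    return parent, lnz


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, lnz):
    """Up-looking numeric LDL'; A upper-triangular CSC with diagonal."""
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + lnz[k]
    Li = np.zeros(Lp[n], dtype=np.int64)
    Lx = np.zeros(Lp[n])
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnext = Lp[:n].copy()  # next free slot per column
    for k in range(n):
        top = n
        flag[k] = k
        Y[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = pattern[top]
            top += 1
            yi = Y[i]
            Y[i] = 0.0
            for p in range(Lp[i], lnext[i]):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[lnext[i]] = k
            Lx[lnext[i]] = l_ki
            lnext[i] += 1
    return Lp, Li, Lx, D


@njit(cache=True)
def _ldl_solve(n, Lp, Li, Lx, D, b):
    x = b.copy()
    for j in range(n):
        xj = x[j]
        for p in range(Lp[j], Lp[j + 1]):
            x[Li[p]] -= Lx[p] * xj
    for j in range(n):
        x[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = x[j]
        for p in range(Lp[j], Lp[j + 1]):
            s -= Lx[p] * x[Li[p]]
        x[j] = s
    return x


@njit(cache=True)
def _takahashi(n, Lp, Li, Lx, D):
    """Selected inverse on the pattern of L (+ diagonal).

    Columns processed right to left:
        Z_ij = -sum_k L_kj Z_(i,k)   (i, k in struct L(:,j), k > j)
        Z_jj = 1/d_j - sum_k L_kj Z_kj
    Every referenced Z_(i,k) lies in the clique of column j of the filled
    (chordal) graph, so it is already stored in a later column of Z.
    Contributions are accumulated by scanning each referenced column once
    (both orientations of each symmetric entry), with a scatter workspace
    instead of per-entry searches.
    """
    Zx = np.zeros(Lp[n])
    Zd = np.zeros(n)
    flag = np.full(n, -1, dtype=np.int64)
    lval = np.zeros(n)
    acc = np.zeros(n)
    for j in range(n - 1, -1, -1):
        p0, p1 = Lp[j], Lp[j + 1]
        for p in range(p0, p1):
            r = Li[p]
            flag[r] = j
            lval[r] = Lx[p]
            acc[r] = 0.0
        for p in range(p0, p1):
            k = Li[p]
            lkj = lval[k]
            acc[k] -= lkj * Zd[k]
            for q in range(Lp[k], Lp[k + 1]):
                r = Li[q]
                if flag[r] == j:
                    z = Zx[q]          # z = Z_rk = Z_kr, r > k
                    acc[r] -= lkj * z
                    acc[k] -= lval[r] * z
        s = 1.0 / D[j]
        for p in range(p0, p1):
            r = Li[p]
            Zx[p] = acc[r]
            s -= lval[r] * acc[r]
        Zd[j] = s
    return Zx, Zd


@njit(cache=True)
def _gather(Lp, Li, Zx, Zd, rows, cols, out):
    for t in range(rows.shape[0]):
        i, j = rows[t], cols[t]
        if i == j:
            out[t] = Zd[i]
            continue
        if i < j:
            i, j = j, i
        lo, hi = Lp[j], Lp[j + 1]
        v = np.nan
        while lo < hi:
            mid = (lo + hi) // 2
            if Li[mid] == i:
                v = Zx[mid]
                break
            elif Li[mid] < i:
                lo = mid + 1
            else:
                hi = mid
        out[t] = v


class SparseLDL:
    """LDL' factor of a symmetric positive-definite sparse matrix with
    on-pattern selected inverse.

    Entries of the inverse may be queried for any (i, j) on the nonzero
    pattern of the input matrix (or its fill); querying an off-pattern
    entry returns NaN, which callers treat as a contract breach.
    """

    def __init__(self, m: sparse.spmatrix, perm: np.ndarray | None = None):
        m = sparse.csc_matrix(m)
        n = m.shape[0]
        self.n = n
        candidates = ([np.asarray(perm, dtype=np.int64)] if perm is not None
                      else [p for p in (fill_reducing_permutation(m),
                                        np.arange(n, dtype=np.int64))])
        best = None
        for cand in candidates:
            mp = m[cand][:, cand]
            up = sparse.triu(mp, format="csc")
            up.sort_indices()
            parent, lnz = _ldl_symbolic(n, up.indptr.astype(np.int64), up.indices.astype(np.int64))
            fill = int(lnz.sum())
            if best is None or fill < best[0]:
                best = (fill, cand, up, parent, lnz)
        _, self.perm, up, parent, lnz = best
        self.up_indptr = up.indptr.astype(np.int64)
        self.up_indices = up.indices.astype(np.int64)
        self.parent, self.lnz = parent, lnz
        self._finish(up.data.astype(np.float64))

    def _finish(self, up_data: np.ndarray) -> None:
        n = self.n
        self.iperm = np.empty(n, dtype=np.int64)
        self.iperm[self.perm] = np.arange(n)
        self.Lp, self.Li, self.Lx, self.D = _ldl_numeric(
            n, self.up_indptr, self.up_indices, up_data, self.parent, self.lnz)
        if not np.all(np.isfinite(self.D)) or not np.all(self.D > 0):
            raise np.linalg.LinAlgError("matrix not positive definite")
        self._Zx = None
        self._Zd = None

    def refactor(self, up_data: np.ndarray) -> "SparseLDL":
        """New factorization of a matrix with the same permuted upper
        structure (cheap: symbolic analysis and ordering are reused)."""
        out = SparseLDL.__new__(SparseLDL)
        out.n = self.n
        out.perm = self.perm
        out.up_indptr = self.up_indptr
        out.up_indices = self.up_indices
        out.parent, out.lnz = self.parent, self.lnz
        out._finish(up_data)
        return out

    @property
    def nnz_factor(self) -> int:
        return int(self.Lp[-1])

    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            return _ldl_solve(self.n, self.Lp, self.Li, self.Lx, self.D,
                              b[self.perm])[self.iperm]
        out = np.empty_like(b)
        for k in range(b.shape[1]):
            out[:, k] = self.solve(b[:, k])
        return out

    def _ensure_selected_inverse(self) -> None:
        if self._Zx is None:
            self._Zx, self._Zd = _takahashi(self.n, self.Lp, self.Li, self.Lx, self.D)

    def inv_entries(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Entries of the inverse at (rows, cols); NaN if off-pattern."""
        self._ensure_selected_inverse()
        rows = self.iperm[np.asarray(rows, dtype=np.int64)]
        cols = self.iperm[np.asarray(cols, dtype=np.int64)]
        out = np.empty(len(rows))
        _gather(self.Lp, self.Li, self._Zx, self._Zd, rows, cols, out)
        return out
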