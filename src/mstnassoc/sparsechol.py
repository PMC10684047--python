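"""Sparse symmetric LDL' factorisation for mixed-model equations.

Henderson systems for herd-structured cattle data are large but almost
block-diagonal: most equations (contemporary groups, dams, calves, permanent
environment) touch a single herd, while a few hub columns (widely used AI
sires, dense covariates such as breed fractions) couple everything.  General
sparse LU solvers order these hubs poorly and the factorisation explodes;
the classical remedy, used here, is a minimum-degree ordering in which hub
columns are eliminated last.

The factorisation is split into a symbolic phase (elimination tree, row
patterns, ordering) computed once per model structure, and a cheap numeric
phase re-run at every REML likelihood evaluation.  The matrix must be
symmetric positive definite; the ordering affects speed only, never
correctness.
"""

from __future__ import annotations

import heapq

import numpy as np
import scipy.sparse as sp
from numba import njit


@njit(cache=True)
def _etree(n, Ap, Ai):
    parent = np.full(n, -1, np.int64)
    ancestor = np.full(n, -1, np.int64)
    for k in range(n):
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i != -1 and i < k:
                inext = ancestor[i]
                ancestor[i] = k
                if inext == -1:
                    parent[i] = k
                i = inext
    return parent


@njit(cache=True)
def _symbolic(n, Ap, Ai, parent):
    mark = np.full(n, -1, np.int64)
    colcount = np.zeros(n, np.int64)
    rowptr = np.zeros(n + 1, np.int64)
    for k in range(n):
        mark[k] = k
        cnt = 0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i >= k:
                continue
            while mark[i] != k:
                mark[i] = k
                cnt += 1
                i = parent[i]
        rowptr[k + 1] = cnt
    for k in range(n):
        rowptr[k + 1] += rowptr[k]
    rowind = np.zeros(rowptr[n], np.int64)
    mark[:] = -1
    stack = np.zeros(n, np.int64)
    for k in range(n):
        mark[k] = k
        dest = rowptr[k]
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i >= k:
                continue
            ln = 0
            while mark[i] != k:
                mark[i] = k
                stack[ln] = i
                ln += 1
                i = parent[i]
            for q in range(ln - 1, -1, -1):
                rowind[dest] = stack[q]
                dest += 1
        seg = rowind[rowptr[k]:rowptr[k + 1]]
        seg.sort()
        for idx in seg:
            colcount[idx] += 1
    return rowptr, rowind, colcount


@njit(cache=True)
def _numeric(n, Ap, Ai, Ax, rowptr, rowind, colcount, Lp, Li, Lx, D):
    """Up-looking LDL'; A given as upper triangle (CSC, sorted).  Returns
    False if a non-positive pivot is met (matrix not positive definite)."""
    Lnz = np.zeros(n, np.int64)
    y = np.zeros(n)
    for k in range(n):
        dk = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                y[i] = Ax[p]
            elif i == k:
                dk = Ax[p]
        for q in range(rowptr[k], rowptr[k + 1]):
            j = rowind[q]
            yj = y[j]
            y[j] = 0.0
            lkj = yj / D[j]
            for t in range(Lp[j], Lp[j] + Lnz[j]):
                y[Li[t]] -= Lx[t] * yj
            dk -= lkj * yj
            Li[Lp[j] + Lnz[j]] = k
            Lx[Lp[j] + Lnz[j]] = lkj
            Lnz[j] += 1
        if dk <= 0.0:
            return False
        D[k] = dk
    return True


@njit(cache=True)
def _solve1(n, Lp, Li, Lx, D, b):
    x = b.copy()
    for j in range(n):
        xj = x[j]
        if xj != 0.0:
            for t in range(Lp[j], Lp[j + 1]):
                x[Li[t]] -= Lx[t] * xj
    for j in range(n):
        x[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = x[j]
        for t in range(Lp[j], Lp[j + 1]):
            s -= Lx[t] * x[Li[t]]
        x[j] = s
    return x


@njit(cache=True)
def _solve_multi(n, Lp, Li, Lx, D, B):
    X = B.copy()
    m = B.shape[1]
    for j in range(n):
        for t in range(Lp[j], Lp[j + 1]):
            i = Li[t]
            l = Lx[t]
            for c in range(m):
                X[i, c] -= l * X[j, c]
    for j in range(n):
        dj = D[j]
        for c in range(m):
            X[j, c] /= dj
    for j in range(n - 1, -1, -1):
        for t in range(Lp[j], Lp[j + 1]):
            i = Li[t]
            l = Lx[t]
            for c in range(m):
                X[j, c] -= l * X[i, c]
    return X


def minimum_degree_order(C: sp.spmatrix, hub_cutoff: int | None = None) -> np.ndarray:
    """Symmetric fill-reducing permutation.

    Plain minimum-degree (explicit elimination graph, lazy heap) on the
    low-degree subgraph; hub columns with degree >= hub_cutoff are excluded
    from the graph and appended last in ascending degree.  Deterministic.
    """
    m = C.shape[0]
    Cc = C.tocsr()
    deg0 = np.diff(Cc.indptr) - 1
    if hub_cutoff is None:
        hub_cutoff = max(64, 8 * int(np.median(deg0)) + 1)
    hubs = np.where(deg0 >= hub_cutoff)[0]
    hubset = set(hubs.tolist())
    adj: dict[int, set] = {}
    for j in range(m):
        if j in hubset:
            continue
        nb = Cc.indices[Cc.indptr[j]:Cc.indptr[j + 1]]
        adj[j] = {int(x) for x in nb if x != j and int(x) not in hubset}
    heap = [(len(s), j) for j, s in adj.items()]
    heapq.heapify(heap)
    order = []
    dead = set()
    while heap:
        dg, u = heapq.heappop(heap)
        if u in dead:
            continue
        su = adj[u]
        if len(su) != dg:  # stale key: re-queue with the current degree
            heapq.heappush(heap, (len(su), u))
            continue
        order.append(u)
        dead.add(u)
        for v in su:
            sv = adj[v]
            sv.discard(u)
            before = len(sv)
            sv.update(su)
            sv.discard(v)
            if len(sv) != before:
                heapq.heappush(heap, (len(sv), v))
        del adj[u]
    order.extend(int(h) for h in hubs[np.argsort(deg0[hubs], kind="stable")])
    perm = np.asarray(order, dtype=np.int64)
    assert len(perm) == m and len(set(order)) == m
    return perm


class SymbolicLDL:
    """Reusable symbolic factorisation of a fixed sparsity pattern.

    Built once from any matrix carrying the pattern; ``factor(values_csc)``
    then runs the numeric phase for new values on the same pattern.
    """

    def __init__(self, C: sp.spmatrix, perm: np.ndarray | None = None):
        C = sp.csc_matrix(C)
        self.n = C.shape[0]
        self.perm = minimum_degree_order(C) if perm is None else np.asarray(perm, np.int64)
        self.iperm = np.empty_like(self.perm)
        self.iperm[self.perm] = np.arange(self.n)
        P = sp.csr_matrix(
            (np.ones(self.n), (np.arange(self.n), self.perm)), shape=(self.n, self.n))
        Cp = (P @ C @ P.T).tocsc()
        Cp.sort_indices()
        U = sp.triu(Cp, format="csc")
        U.sort_indices()
        self._Ap = U.indptr.astype(np.int64)
        self._Ai = U.indices.astype(np.int64)
        # mapping from the original CSC data layout to the permuted upper data
        coo = C.tocoo()
        pi, pj = self.iperm[coo.row], self.iperm[coo.col]
        keep = pi <= pj
        key = pj[keep].astype(np.int64) * self.n + pi[keep]
        ukey = self._repeat_keys(U)
        lookup = {k: s for s, k in enumerate(ukey)}
        self._src = np.where(keep)[0]
        self._slot = np.array([lookup[k] for k in key], dtype=np.int64)
        self._nu = U.nnz
        parent = _etree(self.n, self._Ap, self._Ai)
        self._rowptr, self._rowind, self._colcount = _symbolic(
            self.n, self._Ap, self._Ai, parent)
        self._Lp = np.zeros(self.n + 1, np.int64)
        np.cumsum(self._colcount, out=self._Lp[1:])
        self.fill = int(self._Lp[-1])

    @staticmethod
    def _repeat_keys(U):
        n = U.shape[0]
        cols = np.repeat(np.arange(n), np.diff(U.indptr))
        return cols.astype(np.int64) * n + U.indices

    def factor(self, C: sp.spmatrix) -> "NumericLDL":
        """Numeric factorisation of a matrix with the symbolic pattern."""
        data = sp.csc_matrix(C).tocoo().data  # same construction order as init
        ux = np.zeros(self._nu)
        np.add.at(ux, self._slot, data[self._src])
        return self._factor_values(ux)

    def factor_from_upper(self, upper_data: np.ndarray) -> "NumericLDL":
        return self._factor_values(upper_data)

    def coo_slots(self, rows, cols) -> np.ndarray:
        """Precompute, for fixed COO coordinates (original indexing, upper or
        both triangles), the destination slot of each triplet in the permuted
        upper data array.  With these slots a numeric reassembly is just
        ``np.bincount(slots, weights=vals, minlength=self.upper_nnz)``.

        Lower-triangle duplicates of symmetric input must be filtered by the
        caller (or values halved); only (i, j) with permuted i <= j map to a
        unique slot here, and both orders map to the same slot.
        """
        pi, pj = self.iperm[np.asarray(rows)], self.iperm[np.asarray(cols)]
        lo = np.minimum(pi, pj)
        hi = np.maximum(pi, pj)
        key = hi.astype(np.int64) * self.n + lo
        ukeys = np.repeat(
            np.arange(self.n), np.diff(self._Ap)).astype(np.int64) * self.n + self._Ai
        slots = np.searchsorted(ukeys, key)
        if np.any(ukeys[np.clip(slots, 0, len(ukeys) - 1)] != key):
            raise ValueError("triplet outside the symbolic pattern")
        return slots

    @property
    def upper_nnz(self) -> int:
        return self._nu

    def _factor_values(self, ux: np.ndarray) -> "NumericLDL":
        Li = np.zeros(self._Lp[-1], np.int64)
        Lx = np.zeros(self._Lp[-1])
        D = np.zeros(self.n)
        ok = _numeric(self.n, self._Ap, self._Ai, ux, self._rowptr,
                      self._rowind, self._colcount, self._Lp, Li, Lx, D)
        if not ok:
            raise np.linalg.LinAlgError("matrix is not positive definite")
        return NumericLDL(self, Li, Lx, D)


class NumericLDL:
    def __init__(self, sym: SymbolicLDL, Li, Lx, D):
        self._sym = sym
        self._Li, self._Lx, self._D = Li, Lx, D

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        s = self._sym
        if b.ndim == 1:
            x = _solve1(s.n, s._Lp, self._Li, self._Lx, self._D, b[s.perm])
            return x[s.iperm]
        X = _solve_multi(s.n, s._Lp, self._Li, self._Lx, self._D,
                         np.ascontiguousarray(b[s.perm]))
        return X[s.iperm]
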