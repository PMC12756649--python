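"""Sparse LDL' machinery for the mixed-model equations.

Animal-model coefficient matrices are symmetric positive definite but very
sensitive to elimination order: pedigree graphs with shared sires create
large cliques under naive orderings.  This module provides

* :func:`min_degree_order` — a quotient-graph minimum-degree ordering over
  column *groups* (all equations of one animal move together), the same
  family of heuristics sparse Cholesky libraries use;
* :class:`LDLFactor` — an up-looking simplicial LDL' factorisation with a
  symbolic analysis that is done once per sparsity pattern and a fast
  numeric refactorisation for every new set of matrix values (compiled with
  numba), plus triangular solves and the log-determinant.

The factorisation is for SPD systems; a non-positive pivot signals a
parameter outside the admissible region and raises.
"""

from __future__ import annotations

import heapq

import numpy as np
import scipy.sparse as sp
from numba import njit


# ---------------------------------------------------------------------------
# ordering


def min_degree_order(adj: list[set], weight: np.ndarray | None = None) -> np.ndarray:
    """Approximate minimum-degree ordering of an undirected graph.

    ``adj`` is destroyed.  Uses a quotient-graph representation (eliminated
    vertices become elements whose boundaries stand in for their cliques)
    with a lazy heap; degrees are weighted by ``weight`` so that a vertex
    standing for a group of k columns counts k.
    """
    n = len(adj)
    w = np.ones(n, np.int64) if weight is None else np.asarray(weight, np.int64)
    elements: dict[int, set] = {}
    var_elems: list[set] = [set() for _ in range(n)]
    alive = np.ones(n, bool)

    def exact_neighbors(v):
        s = set(adj[v])
        for e in var_elems[v]:
            s |= elements[e]
        s.discard(v)
        return {u for u in s if alive[u]}

    heap = [(int(sum(w[u] for u in adj[v])), v) for v in range(n)]
    heapq.heapify(heap)
    order = []
    while heap:
        d, v = heapq.heappop(heap)
        if not alive[v]:
            continue
        nbrs = exact_neighbors(v)
        dv = int(sum(w[u] for u in nbrs))
        if dv > d:
            heapq.heappush(heap, (dv, v))
            continue
        alive[v] = False
        order.append(v)
        absorbed = var_elems[v]
        elements[v] = nbrs
        for e in absorbed:
            if e in elements and e != v:
                del elements[e]
        for u in nbrs:
            adj[u].discard(v)
            adj[u] -= nbrs
            var_elems[u] = {e for e in var_elems[u] if e in elements}
            var_elems[u].add(v)
            du = int(
                sum(w[x] for x in adj[u])
                + sum(sum(w[x] for x in elements[e]) for e in var_elems[u])
            )
            heapq.heappush(heap, (du, u))
    return np.asarray(order, np.int64)


def grouped_fill_reducing_permutation(
    C: sp.spmatrix, groups: list[np.ndarray], dense_groups: np.ndarray | None = None
) -> np.ndarray:
    """Column permutation of C from a minimum-degree ordering of its group
    quotient graph; columns of one group stay adjacent.

    ``dense_groups`` marks hub groups (fixed-effect columns, connected to
    nearly everything); they are excluded from the elimination graph and
    ordered last, the standard treatment of dense rows.  The sparse part is
    first peeled of degree-<=2 groups (leaf animals fall out in droves),
    then minimum degree orders the remainder.
    """
    import collections

    n = C.shape[0]
    gid = np.full(n, -1, np.int64)
    for g, cols in enumerate(groups):
        gid[np.asarray(cols)] = g
    assert (gid >= 0).all(), "groups must cover all columns"
    ng = len(groups)
    if dense_groups is None:
        dense_groups = np.zeros(ng, bool)
    Cc = C.tocoo()
    adj: list[set] = [set() for _ in range(ng)]
    gr = gid[Cc.row]
    gc = gid[Cc.col]
    mask = gr != gc
    for a, b in zip(gr[mask], gc[mask]):
        if not (dense_groups[a] or dense_groups[b]):
            adj[a].add(int(b))

    alive = ~dense_groups
    peel: list[int] = []
    queue = collections.deque(g for g in range(ng) if alive[g] and len(adj[g]) <= 2)
    while queue:
        v = queue.popleft()
        if not alive[v] or len(adj[v]) > 2:
            continue
        nb = list(adj[v])
        alive[v] = False
        peel.append(v)
        for u in nb:
            adj[u].discard(v)
        if len(nb) == 2:
            a, b = nb
            adj[a].add(b)
            adj[b].add(a)
        for u in nb:
            if len(adj[u]) <= 2:
                queue.append(u)

    rem = [g for g in range(ng) if alive[g]]
    rmap = {g: i for i, g in enumerate(rem)}
    sub = [set(rmap[u] for u in adj[g] if alive[u]) for g in rem]
    w = np.array([len(groups[g]) for g in rem], np.int64)
    sub_order = min_degree_order(sub, w) if rem else np.array([], np.int64)
    tail = [g for g in range(ng) if dense_groups[g]]
    full = peel + [rem[i] for i in sub_order] + tail
    perm = np.concatenate([np.asarray(groups[g]) for g in full])
    return perm.astype(np.int64)


# ---------------------------------------------------------------------------
# LDL' factorisation (Davis-style up-looking, symbolic + numeric split)


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai, parent, Lnz, flag):
    for k in range(n):
        parent[k] = -1
        flag[k] = k
        Lnz[k] = 0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                flag[i] = k
                Lnz[i] += 1
                i = parent[i]


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, Lp, parent, Lnz, Li, Lx, D, Y, pattern, flag):
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        Lnz[k] = 0
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
                top -= 1
                length -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = pattern[top]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + Lnz[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[p2] = k
            Lx[p2] = l_ki
            Lnz[i] += 1
            top += 1
        if D[k] == 0.0:
            return k
    return -1


@njit(cache=True)
def _ldl_solve(n, Lp, Li, Lx, Lnz, D, x):
    for j in range(n):
        xj = x[j]
        for p in range(Lp[j], Lp[j] + Lnz[j]):
            x[Li[p]] -= Lx[p] * xj
    for j in range(n):
        x[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = x[j]
        for p in range(Lp[j], Lp[j] + Lnz[j]):
            s -= Lx[p] * x[Li[p]]
        x[j] = s


@njit(cache=True)
def _takahashi(n, Lp, Li, Lx, Lnz, D, Zx):
    """Selected inverse on the pattern of L (plus diagonal, stored in Zd).

    Returns Zd (diagonal of the inverse) and fills Zx aligned with (Li, Lx):
    Zx[p] = (C^-1)[Li[p], j] for p in column j's range.  The factor pattern
    is closed under the Takahashi recurrences, so all required intermediate
    entries are available.  Scatter-based: column j's recurrence

        Z[i, j] = -sum_k L[k, j] Z[i, k],   i, k in pattern(col j)

    is accumulated by walking the already-computed Z columns k and using a
    dense membership mark instead of per-entry searches.
    """
    Zd = np.empty(n)
    lval = np.zeros(n)
    acc = np.zeros(n)
    mark = np.full(n, -1, np.int64)
    for j in range(n - 1, -1, -1):
        p0, p1 = Lp[j], Lp[j] + Lnz[j]
        for p in range(p0, p1):
            i = Li[p]
            lval[i] = Lx[p]
            mark[i] = j
            acc[i] = 0.0
        for p in range(p0, p1):
            k = Li[p]
            lk = lval[k]
            # diagonal of column k
            acc[k] += lk * Zd[k]
            q0, q1 = Lp[k], Lp[k] + Lnz[k]
            for q in range(q0, q1):
                i = Li[q]
                if mark[i] == j:
                    z = Zx[q]
                    acc[i] += lk * z
                    acc[k] += lval[i] * z
        s = 1.0 / D[j]
        for p in range(p0, p1):
            zij = -acc[Li[p]]
            Zx[p] = zij
            s -= Lx[p] * zij
        Zd[j] = s
    return Zd


class NotPositiveDefiniteMatrix(ValueError):
    pass


@njit(cache=True)
def _csr_lookup(indptr, indices, rows, cols, out):
    """out[t] = position of (rows[t], cols[t]) in a sorted CSR; -1 if absent."""
    for t in range(rows.size):
        r = rows[t]
        lo, hi = indptr[r], indptr[r + 1]
        c = cols[t]
        pos = -1
        while lo < hi:
            mid = (lo + hi) // 2
            v = indices[mid]
            if v < c:
                lo = mid + 1
            elif v > c:
                hi = mid
            else:
                pos = mid
                break
        out[t] = pos
    return out


class LDLFactor:
    """Simplicial LDL' of a permuted SPD matrix with reusable symbolic analysis."""

    def __init__(self, C: sp.spmatrix, perm: np.ndarray):
        self.n = C.shape[0]
        self.perm = np.asarray(perm, np.int64)
        self.iperm = np.argsort(self.perm)
        Ccsr = C.tocsr()
        Ccsr.sort_indices()
        self._nnz_C = Ccsr.nnz
        Cp = Ccsr[self.perm][:, self.perm].tocsc()
        Cp.sort_indices()
        # keep upper triangle (row <= col) in CSC
        U = sp.triu(Cp, format="csc")
        U.sort_indices()
        self.Ap, self.Ai = U.indptr.astype(np.int64), U.indices.astype(np.int64)
        n = self.n
        # value-gather map: permuted-upper entry t comes from Ccsr.data[_gather[t]]
        ucols = np.repeat(np.arange(n, dtype=np.int64), np.diff(self.Ap))
        orow = self.perm[self.Ai]
        ocol = self.perm[ucols]
        self._gather = np.empty(self.Ai.size, np.int64)
        _csr_lookup(
            Ccsr.indptr.astype(np.int64), Ccsr.indices.astype(np.int64),
            orow, ocol, self._gather,
        )
        if np.any(self._gather < 0):
            raise ValueError("inconsistent sparsity while building the factor")
        self.parent = np.empty(n, np.int64)
        self._Lnz = np.empty(n, np.int64)
        self._flag = np.empty(n, np.int64)
        _ldl_symbolic(n, self.Ap, self.Ai, self.parent, self._Lnz, self._flag)
        self.Lp = np.zeros(n + 1, np.int64)
        np.cumsum(self._Lnz, out=self.Lp[1:])
        nnzL = int(self.Lp[-1])
        self.Li = np.empty(nnzL, np.int64)
        self.Lx = np.empty(nnzL)
        self.D = np.empty(n)
        self._Y = np.empty(n)
        self._pattern = np.empty(n, np.int64)
        self.nnz_L = nnzL
        self.refactor(C)

    def refactor(self, C: sp.spmatrix) -> "LDLFactor":
        """Numeric refactorisation for new values on the same pattern."""
        Ccsr = C.tocsr()
        if Ccsr.nnz != self._nnz_C:
            raise ValueError("sparsity pattern changed; build a new factor")
        Ccsr.sort_indices()
        return self._refactor_data(Ccsr.data[self._gather])

    def _refactor_data(self, Udata: np.ndarray) -> "LDLFactor":
        bad = _ldl_numeric(
            self.n, self.Ap, self.Ai, Udata, self.Lp, self.parent,
            self._Lnz, self.Li, self.Lx, self.D, self._Y, self._pattern, self._flag,
        )
        if bad >= 0 or np.any(self.D <= 0.0):
            raise NotPositiveDefiniteMatrix(
                "matrix is not positive definite (pivot failure)"
            )
        return self

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = np.array(b[self.perm], dtype=float)
        _ldl_solve(self.n, self.Lp, self.Li, self.Lx, self._Lnz, self.D, x)
        return x[self.iperm]

    def takahashi(self):
        """Selected inverse on the factor pattern.

        Returns (Zd, Zx): Zd[j] = (C^-1)_{jj} in *permuted* coordinates and
        Zx aligned with the factor's (Lp, Li) column storage.
        """
        Zx = np.empty(self.nnz_L)
        Zd = _takahashi(
            self.n, self.Lp, self.Li, self.Lx, self._Lnz, self.D, Zx
        )
        return Zd, Zx

    def selected_inverse_lookup(self, rows: np.ndarray, cols: np.ndarray):
        """Indices to gather (C^-1)[rows, cols] from a takahashi() result.

        Positions are in original (unpermuted) coordinates; every requested
        entry must lie in the factor pattern (true for any entry of C).
        Returns (kind, idx): kind 0 -> diagonal Zd[idx], kind 1 -> Zx[idx].
        """
        pr = self.iperm[np.asarray(rows)]
        pc = self.iperm[np.asarray(cols)]
        a = np.maximum(pr, pc)
        b = np.minimum(pr, pc)
        kind = np.where(a == b, 0, 1).astype(np.int8)
        idx = np.empty(a.size, np.int64)
        # column j of L occupies Lp[j] .. Lp[j+1], rows ascending
        _csr_lookup(self.Lp, self.Li, b, a, idx)
        diag = kind == 0
        idx[diag] = b[diag]
        if np.any(idx[~diag] < 0):
            raise KeyError("entry outside factor pattern")
        return kind, idx
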