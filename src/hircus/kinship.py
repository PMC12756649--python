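"""Autosomal (A) and X-chromosomal (S) relationship matrices and their sparse inverses.

Scaling convention for S (gametic model of Fernando & Grossman):
every X gamete carries additive value with variance ``sigma_s^2 / 2`` in the
base population, a female's X breeding value is the sum of her paternal and
maternal gamete values, and a male's is his single maternal gamete value.
Hence a non-inbred base female has S_ii = 1 and a base male S_ii = 1/2, and
``sigma_s^2`` is the base-population *female* X-linked additive variance.
No dosage-compensation multiplier is applied.

Recursion used throughout (pedigree sorted, parents first):

* female i:  x_i = x_sire + 0.5 * x_dam + phi_i
* male i:    x_i = 0.5 * x_dam + phi_i          (sires pass no X to sons)

with Mendelian sampling variances ``d_i`` given by :func:`xlinked_msv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import FEMALE, MALE, Pedigree, PedigreeError, _require_sorted, inbreeding


@dataclass
class RelationshipMatrix:
    """Symmetric PSD relationship matrix over the animals of a sorted pedigree."""

    kind: str  # "autosomal_A" | "xlinked_S"
    order: np.ndarray  # animal ids, row/column order
    values: np.ndarray  # dense symmetric matrix
    inverse: sp.spmatrix | None = None

    def to_triplets(self) -> np.ndarray:
        """Lower-triangle (i, j, value) triplets, 1-based indices."""
        n = self.values.shape[0]
        i, j = np.tril_indices(n)
        v = self.values[i, j]
        keep = v != 0.0
        return np.column_stack([i[keep] + 1, j[keep] + 1, v[keep]])


# ---------------------------------------------------------------------------
# autosomal


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method."""
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix("autosomal_A", ped.animals.copy(), A)


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Per-animal autosomal Mendelian sampling variance d_i.

    d_i = 1 - 0.25(1+F_sire) - 0.25(1+F_dam), terms dropped when the parent
    is unknown.
    """
    sire, dam = ped.parent_indices()
    d = np.ones(len(ped))
    known_s = sire >= 0
    known_d = dam >= 0
    d[known_s] -= 0.25 * (1.0 + F[sire[known_s]])
    d[known_d] -= 0.25 * (1.0 + F[dam[known_d]])
    return d


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding."""
    _require_sorted(ped)
    if F is None:
        F = inbreeding(ped)
    sire, dam = ped.parent_indices()
    n = len(ped)
    d = mendelian_sampling_variance(ped, F)
    if np.any(d <= 0):
        bad = ped.animals[np.argmax(d <= 0)]
        raise PedigreeError(f"non-positive Mendelian sampling variance at animal {bad!r}")
    rows, cols, vals = [], [], []
    for i in range(n):
        ent = [(i, 1.0)]
        if sire[i] >= 0:
            ent.append((sire[i], -0.5))
        if dam[i] >= 0:
            ent.append((dam[i], -0.5))
        w = 1.0 / d[i]
        for a, ca in ent:
            for b, cb in ent:
                rows.append(a)
                cols.append(b)
                vals.append(ca * cb * w)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def logdet_A(ped: Pedigree, F: np.ndarray | None = None) -> float:
    """log det A = sum(log d_i) from the generalized Cholesky of A."""
    if F is None:
        F = inbreeding(ped)
    return float(np.sum(np.log(mendelian_sampling_variance(ped, F))))


# ---------------------------------------------------------------------------
# X-linked


def _xlinked_regression(ped: Pedigree):
    """Per-animal parent regression coefficients of the X-linked recursion.

    Returns (coef_sire, coef_dam): females regress with (1, 0.5), males with
    (0, 0.5); unknown parents get 0.
    """
    sire, dam = ped.parent_indices()
    sex = ped.sex_codes
    cs = np.where((sex == FEMALE) & (sire >= 0), 1.0, 0.0)
    cd = np.where(dam >= 0, 0.5, 0.0)
    return cs, cd


def xlinked_inbreeding(ped: Pedigree) -> np.ndarray:
    """X-linked inbreeding Fx_i per animal.

    For a female, the probability her two X chromosomes are IBD.  On the
    package's scale this equals S(sire, dam): the paternal gamete is the
    sire's whole X (value variance 1/2) and the maternal one a draw from
    the dam, so r(pat, mat) = Cov(x_sire, t_dam) / (1/2) = S(sire, dam).
    Zero for males and for females with an unknown parent.  Computed with the S recursion restricted to ancestor
    pairs (memoized recursive co-ancestry), so no dense matrix is formed.
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    sex = ped.sex_codes
    cs, cd = _xlinked_regression(ped)

    import sys
    cache: dict[tuple[int, int], float] = {}
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 10 * len(ped) + 1000))

    def S_pair(i: int, j: int) -> float:
        # S entry between distinct animals i > j (recurse on the younger)
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return self_S(i)
        if i < j:
            i, j = j, i
        key = (i, j)
        v = cache.get(key)
        if v is None:
            v = cs[i] * S_pair(sire[i], j) + cd[i] * S_pair(dam[i], j)
            cache[key] = v
        return v

    self_cache: dict[int, float] = {}

    def self_S(i: int) -> float:
        v = self_cache.get(i)
        if v is None:
            if sex[i] == MALE:
                v = 0.5
            elif sire[i] >= 0 and dam[i] >= 0:
                v = 1.0 + S_pair(sire[i], dam[i])
            else:
                v = 1.0
            self_cache[i] = v
        return v

    Fx = np.zeros(len(ped))
    for i in range(len(ped)):
        if sex[i] == FEMALE and sire[i] >= 0 and dam[i] >= 0:
            Fx[i] = S_pair(sire[i], dam[i])
    sys.setrecursionlimit(limit)
    return Fx


def xlinked_msv(ped: Pedigree, Fx: np.ndarray | None = None) -> np.ndarray:
    """Per-animal X-linked Mendelian sampling variance d_i.

    females: both parents known  1/4 - Fx_dam/4
             sire only           1/2
             dam only            3/4 - Fx_dam/4
             founder             1
    males:   dam known           1/4 - Fx_dam/4
             founder             1/2
    The sire-dam relationship cancels out of the female recursion, so d_i
    depends only on the dam's X-linked inbreeding (mirroring the autosomal
    rule, where d_i depends only on parental F).
    """
    _require_sorted(ped)
    if Fx is None:
        Fx = xlinked_inbreeding(ped)
    sire, dam = ped.parent_indices()
    sex = ped.sex_codes
    n = len(ped)
    d = np.empty(n)
    for i in range(n):
        dk = dam[i] >= 0
        fxd = Fx[dam[i]] if dk else 0.0
        if sex[i] == MALE:
            d[i] = 0.25 - 0.25 * fxd if dk else 0.5
        else:
            sk = sire[i] >= 0
            if sk and dk:
                d[i] = 0.25 - 0.25 * fxd
            elif sk:
                d[i] = 0.5
            elif dk:
                d[i] = 0.75 - 0.25 * fxd
            else:
                d[i] = 1.0
    return d


def build_S(ped: Pedigree) -> RelationshipMatrix:
    """Dense X-chromosomal relationship matrix by the gametic recursion."""
    _require_sorted(ped)
    if any(s not in (MALE, FEMALE) for s in ped.sex_codes):
        raise PedigreeError("every animal needs a known sex to build S")
    sire, dam = ped.parent_indices()
    cs, cd = _xlinked_regression(ped)
    Fx = xlinked_inbreeding(ped)
    d = xlinked_msv(ped, Fx)
    n = len(ped)
    S = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if cs[i]:
            row += cs[i] * S[sire[i], :i]
        if cd[i]:
            row += cd[i] * S[dam[i], :i]
        S[i, :i] = row
        S[:i, i] = row
        diag = d[i]
        if cs[i]:
            diag += cs[i] * cs[i] * S[sire[i], sire[i]]
        if cd[i]:
            diag += cd[i] * cd[i] * S[dam[i], dam[i]]
        if cs[i] and cd[i]:
            diag += 2.0 * cs[i] * cd[i] * S[sire[i], dam[i]]
        S[i, i] = diag
    return RelationshipMatrix("xlinked_S", ped.animals.copy(), S)


def build_S_inverse(ped: Pedigree, Fx: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse S^-1 from the gametic-model Mendelian sampling rules.

    S^-1 = (I - M)' D^-1 (I - M) where row i of M holds the parent
    regression coefficients (females: sire 1, dam 1/2; males: dam 1/2) and
    D = diag(d_i) from :func:`xlinked_msv`.
    """
    _require_sorted(ped)
    if any(s not in (MALE, FEMALE) for s in ped.sex_codes):
        raise PedigreeError("every animal needs a known sex to build S inverse")
    sire, dam = ped.parent_indices()
    cs, cd = _xlinked_regression(ped)
    d = xlinked_msv(ped, Fx)
    if np.any(d <= 1e-14):
        bad = ped.animals[np.argmax(d <= 1e-14)]
        raise PedigreeError(f"singular X-linked sampling variance at animal {bad!r}")
    n = len(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        ent = [(i, 1.0)]
        if cs[i]:
            ent.append((sire[i], -cs[i]))
        if cd[i]:
            ent.append((dam[i], -cd[i]))
        w = 1.0 / d[i]
        for a, ca in ent:
            for b, cb in ent:
                rows.append(a)
                cols.append(b)
                vals.append(ca * cb * w)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def logdet_S(ped: Pedigree, Fx: np.ndarray | None = None) -> float:
    return float(np.sum(np.log(xlinked_msv(ped, Fx))))


# ---------------------------------------------------------------------------
# gene dropping oracle


def gene_drop_oracle(
    ped: Pedigree, n_reps: int, seed: int, chunk: int = 20_000
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimates of A and S by allelic descent.

    Autosomal: two alleles per animal, each parent transmits one of its two
    uniformly; unknown parents contribute fresh founder alleles.  X-linked:
    females carry two alleles (paternal = the sire's single X, intact),
    males one (sampled from the dam).  Allelic effects are i.i.d. normal
    with variance 1/2, so empirical covariances of summed effects estimate
    A and S directly in the package's base-population units.

    Returns (A_hat, S_hat), each n x n.  Monte-Carlo standard error of entry
    (i, j) is approximately sqrt((K_ii K_jj + K_ij^2) / n_reps).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    sex = ped.sex_codes
    n = len(ped)
    rng = np.random.default_rng(seed)
    A_acc = np.zeros((n, n))
    S_acc = np.zeros((n, n))
    done = 0
    half = np.sqrt(0.5)
    while done < n_reps:
        m = min(chunk, n_reps - done)
        # autosomal: per-animal paternal/maternal allele values
        pat = np.empty((n, m))
        mat = np.empty((n, m))
        for i in range(n):
            for arr, p in ((pat, sire[i]), (mat, dam[i])):
                if p < 0:
                    arr[i] = rng.normal(0.0, half, m)
                else:
                    pick = rng.integers(0, 2, m, dtype=np.int8).astype(bool)
                    arr[i] = np.where(pick, pat[p], mat[p])
        v = pat + mat
        A_acc += v @ v.T
        # X-linked: females (pat_x, mat_x), males (mat_x only)
        patx = np.zeros((n, m))
        matx = np.empty((n, m))
        for i in range(n):
            dm = dam[i]
            if dm < 0:
                matx[i] = rng.normal(0.0, half, m)
            else:
                if sex[dm] == MALE:
                    raise PedigreeError(f"male recorded as dam: {ped.animals[dm]!r}")
                pick = rng.integers(0, 2, m, dtype=np.int8).astype(bool)
                matx[i] = np.where(pick, patx[dm], matx[dm])
            if sex[i] == FEMALE:
                s = sire[i]
                patx[i] = rng.normal(0.0, half, m) if s < 0 else matx[s]
        vx = patx + matx
        S_acc += vx @ vx.T
        done += m
    return A_acc / n_reps, S_acc / n_reps


def genedrop_mc_se(K: np.ndarray, n_reps: int) -> np.ndarray:
    """Per-entry Monte-Carlo standard error for a gene-dropping estimate of K."""
    d = np.diag(K)
    return np.sqrt((np.outer(d, d) + K**2) / n_reps)
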