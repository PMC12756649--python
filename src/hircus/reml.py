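"""Multivariate REML for pedigree animal models with X-linked and maternal effects.

The restricted log-likelihood is evaluated through Henderson's mixed-model
equations (MME).  With W = [X Z], R the block-diagonal residual covariance
over records and G the block-diagonal random-effect covariance
(Sigma_block kron K_block), the coefficient matrix is

    C = W' R^-1 W + diag(0, G^-1)

and, up to the additive constant -(n - p)/2 log 2pi,

    -2 logL = log|C| + log|G| + log|R| + y' P y,
    y' P y  = y' R^-1 y - rhs' sol.

Maximisation is average-information (AI) REML.  The AI matrix comes from
the working vectors f_k = dV/dtheta_k P y (which need only the current
random-effect solutions, never a dense relationship matrix).  The score is
exact: its trace terms are read off a Takahashi selected inverse of the
factorised coefficient matrix, which also yields the classical EM update
(B_new = (u' K^-1 u + tr(K^-1 C^uu)) / q) used as a guaranteed-ascent
fallback.  Steps are Levenberg-Marquardt damped with gain-ratio control,
variances pinned at a small floor are handled by an active set, and
iteration stops when the predicted Newton gain of the likelihood is
negligible.

Factorisations use an in-package simplicial LDL' (numba) on a
group-quotient minimum-degree ordering in which all effects of one animal
stay together and each dam's permanent-environment column rides with her
block; symbolic analysis is done once per model and reused for every
refactorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .design import DesignMatrices, PedigreeStructures, build_design
from .models import AAG, MGE, ModelSpec, VarianceComponents, aic

LOG2PI = float(np.log(2.0 * np.pi))


class NotPositiveDefinite(ValueError):
    pass


def _chol_or_none(B: np.ndarray):
    try:
        return np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------


class MixedModel:
    """Assembled mixed-model equations for one model structure and data set."""

    def __init__(self, dm: DesignMatrices, structures: PedigreeStructures):
        self.dm = dm
        self.spec = dm.spec
        self.blocks = [b for b in self.spec.blocks() if b[2] != "R"]
        self.n_fix = dm.X.shape[1]
        self.Kinv: dict[str, sp.csr_matrix] = {}
        self.logdetK: dict[str, float] = {}
        off = self.n_fix
        self.offset: dict[str, int] = {}
        parts = [dm.X]
        for name, pairs, structure in self.blocks:
            nl = dm.n_levels[name]
            Ki, ld = structures.inv(structure, nl)
            self.Kinv[name] = Ki.tocsr()
            self.logdetK[name] = ld
            self.offset[name] = off
            off += len(pairs) * nl
            parts.append(dm.Z[name])
        self.n_mme = off
        self.W = sp.hstack(parts, format="csr")
        self.Wcsc = self.W.tocsc()

        # residual pattern bookkeeping: observation rows are record-major
        rec_start = np.zeros(dm.n_records + 1, np.int64)
        np.add.at(rec_start[1:], dm.obs_record, 1)
        rec_start = np.cumsum(rec_start)
        self._rec_start = rec_start
        self._pattern_records = [
            np.where(dm.pattern_of_record == k)[0] for k in range(len(dm.patterns))
        ]
        self._groups = self._column_groups(structures)
        self._ldl = None
        self._current_token = None

    # -- orderings ---------------------------------------------------------
    def _column_groups(self, structures: PedigreeStructures) -> list:
        """Column groups for the fill-reducing ordering: all effects of one
        animal together (a dam's permanent-environment column rides with her
        block); each fixed-effect column is its own group."""
        dm = self.dm
        n_ped = len(structures.ped)
        groups: list[list[int]] = [[] for _ in range(n_ped)]
        for name, pairs, structure in self.blocks:
            nl = dm.n_levels[name]
            base = self.offset[name]
            if structure in ("A", "S"):
                for j in range(len(pairs)):
                    for p in range(n_ped):
                        groups[p].append(base + j * nl + p)
            else:  # I_dam
                pos = {a: i for i, a in enumerate(structures.ped.animals)}
                for j in range(len(pairs)):
                    for k, aid in enumerate(dm.level_ids[name]):
                        groups[pos[aid]].append(base + j * nl + k)
        out = [np.asarray(g, np.int64) for g in groups if g]
        n_anim_groups = len(out)
        out += [np.array([c], np.int64) for c in range(self.n_fix)]
        self._dense_groups = np.zeros(len(out), bool)
        self._dense_groups[n_anim_groups:] = True
        return out

    # -- residual ----------------------------------------------------------
    def rinv(self, Sigma_e: np.ndarray):
        """Block-diagonal R^-1 and log|R| for a residual covariance."""
        dm = self.dm
        rows, cols, vals = [], [], []
        logdetR = 0.0
        for k, pattern in enumerate(dm.patterns):
            obs = list(pattern)
            Sub = Sigma_e[np.ix_(obs, obs)]
            sign, ld = np.linalg.slogdet(Sub)
            if sign <= 0:
                raise NotPositiveDefinite("residual block not positive definite")
            Einv = np.linalg.inv(Sub)
            recs = self._pattern_records[k]
            if recs.size == 0:
                continue
            logdetR += recs.size * ld
            starts = self._rec_start[recs]
            kk = len(obs)
            ii, jj = np.meshgrid(np.arange(kk), np.arange(kk), indexing="ij")
            rows.append((starts[:, None] + ii.ravel()[None, :]).ravel())
            cols.append((starts[:, None] + jj.ravel()[None, :]).ravel())
            vals.append(np.tile(Einv.ravel(), recs.size))
        n = dm.n_obs
        Rinv = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        return Rinv, logdetR

    # -- assembly ----------------------------------------------------------
    def _ginv_triplets(self, vc: VarianceComponents):
        rows, cols, vals = [], [], []
        logdetG = 0.0
        for name, pairs, structure in self.blocks:
            B = vc.blocks[name]
            sign, ld = np.linalg.slogdet(B)
            if sign <= 0:
                raise NotPositiveDefinite(f"block {name} not positive definite")
            Binv = np.linalg.inv(B)
            nl = self.dm.n_levels[name]
            logdetG += nl * ld + len(pairs) * self.logdetK[name]
            K = self.Kinv[name].tocoo()
            base = self.offset[name]
            for a in range(len(pairs)):
                for b in range(len(pairs)):
                    rows.append(base + a * nl + K.row)
                    cols.append(base + b * nl + K.col)
                    vals.append(Binv[a, b] * K.data)
        if not rows:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([]), 0.0
        return (
            np.concatenate(rows),
            np.concatenate(cols),
            np.concatenate(vals),
            logdetG,
        )

    def assemble(self, vc: VarianceComponents):
        Se = vc.blocks["R"]
        Rinv, logdetR = self.rinv(Se)
        WtR = self.Wcsc.T @ Rinv
        Cdata = (WtR @ self.Wcsc).tocoo()
        gr, gc, gv, logdetG = self._ginv_triplets(vc)
        rows = np.concatenate([Cdata.row, gr])
        cols = np.concatenate([Cdata.col, gc])
        vals = np.concatenate([Cdata.data, gv])
        C = sp.coo_matrix((vals, (rows, cols)), shape=(self.n_mme, self.n_mme)).tocsr()
        rhs = WtR @ self.dm.y
        Riy = Rinv @ self.dm.y
        yRy = float(self.dm.y @ Riy)
        return C, rhs, yRy, logdetG, logdetR, Rinv

    def factor(self, vc: VarianceComponents):
        from .sparsechol import (
            LDLFactor,
            NotPositiveDefiniteMatrix,
            grouped_fill_reducing_permutation,
        )

        C, rhs, yRy, logdetG, logdetR, Rinv = self.assemble(vc)
        try:
            if self._ldl is None:
                perm = grouped_fill_reducing_permutation(
                    C, self._groups, self._dense_groups
                )
                self._ldl = LDLFactor(C, perm)
            else:
                self._ldl.refactor(C)
        except NotPositiveDefiniteMatrix as e:
            raise NotPositiveDefinite(str(e)) from e
        token = object()
        self._current_token = token
        self._current_C = C
        logdetC = self._ldl.logdet
        sol = self._ldl.solve(rhs)
        yPy = yRy - float(rhs @ sol)
        n_contrast = self.dm.n_obs - self.n_fix
        logL = -0.5 * (logdetC + logdetG + logdetR + yPy + n_contrast * LOG2PI)
        return _Factor(self, vc, token, sol, logL, Rinv, rhs)

    def _ensure_current(self, fac: "_Factor") -> None:
        if self._current_token is not fac.token:
            C, *_ = self.assemble(fac.vc)
            self._ldl.refactor(C)
            self._current_token = fac.token
            self._current_C = C

    def loglik(self, vc: VarianceComponents) -> float:
        return self.factor(vc).logL


@dataclass
class _Factor:
    mm: MixedModel
    vc: VarianceComponents
    token: object
    sol: np.ndarray
    logL: float
    Rinv: sp.csr_matrix
    rhs: np.ndarray

    def solve(self, b: np.ndarray) -> np.ndarray:
        self.mm._ensure_current(self)
        return self.mm._ldl.solve(b)

    def residuals(self) -> np.ndarray:
        return self.mm.dm.y - self.mm.W @ self.sol

    def block_solution(self, name: str) -> np.ndarray:
        """Random-effect solutions of one block, shape (n_pairs, n_levels)."""
        pairs = self.mm.spec.blocks()
        for nm, prs, structure in pairs:
            if nm == name:
                nl = self.mm.dm.n_levels[name]
                base = self.mm.offset[name]
                return self.sol[base : base + len(prs) * nl].reshape(len(prs), nl)
        raise KeyError(name)

    def fixed_solution(self) -> np.ndarray:
        return self.sol[: self.mm.n_fix]


# ---------------------------------------------------------------------------
# restricted likelihood (public, matches a dense-V evaluation)


def restricted_loglik(
    vc: VarianceComponents, mm: MixedModel | None = None, *, dm=None, structures=None
) -> float:
    """REML log-likelihood of the error contrasts at given components."""
    if mm is None:
        mm = MixedModel(dm, structures)
    return mm.loglik(vc)


# ---------------------------------------------------------------------------
# AI-REML


def _auto_init(mm: MixedModel) -> VarianceComponents:
    """Phenotypic covariance split equally over each trait's random terms + residual."""
    dm = mm.dm
    traits = list(mm.spec.traits)
    tv = dm.records[traits].to_numpy(float)
    P = np.zeros((len(traits), len(traits)))
    for i in range(len(traits)):
        for j in range(len(traits)):
            both = ~np.isnan(tv[:, i]) & ~np.isnan(tv[:, j])
            if both.sum() > 2:
                P[i, j] = np.cov(tv[both, i], tv[both, j])[0, 1]
    nterms = {
        t: 1 + sum(1 for term, trs in mm.spec.random_terms.items() if t in trs)
        for t in traits
    }
    blocks = {}
    for name, pairs, structure in mm.spec.blocks():
        k = len(pairs)
        B = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                ta, tb = traits.index(pairs[a][1]), traits.index(pairs[b][1])
                denom = max(nterms[pairs[a][1]], nterms[pairs[b][1]])
                same_term = pairs[a][0] == pairs[b][0]
                B[a, b] = P[ta, tb] / denom * (1.0 if same_term else 0.1)
        # nudge to strict positive definiteness
        ev = np.linalg.eigvalsh(0.5 * (B + B.T))
        if ev.min() <= 1e-10 * max(abs(ev).max(), 1e-12):
            B = B + (abs(ev.min()) + 1e-6 * np.trace(B) / max(k, 1)) * np.eye(k)
        blocks[name] = 0.5 * (B + B.T)
    vc = VarianceComponents(mm.spec, blocks)
    vc.n_free_parameters = mm.spec.n_parameters()
    return vc


def _param_scales(mm: MixedModel, vc: VarianceComponents) -> np.ndarray:
    traits = list(mm.spec.traits)
    sv = mm.dm.trait_scale
    out = []
    for name, pairs, structure in mm.spec.blocks():
        for i in range(len(pairs)):
            for j in range(i + 1):
                si = sv[traits.index(pairs[i][1])]
                sj = sv[traits.index(pairs[j][1])]
                out.append(np.sqrt(si * sj))
    return np.array(out)


def _is_pd(vc: VarianceComponents) -> bool:
    for nm, pairs, _ in vc.spec.blocks():
        if _chol_or_none(vc.blocks[nm]) is None:
            return False
    return True


def _param_meta(spec: ModelSpec):
    """Per free parameter: (block index, i, j); plus index of each diagonal."""
    meta = []
    diag_of = {}
    for bidx, (nm, pairs, _) in enumerate(spec.blocks()):
        for i in range(len(pairs)):
            for j in range(i + 1):
                if i == j:
                    diag_of[(bidx, i)] = len(meta)
                meta.append((bidx, i, j))
    return meta, diag_of


def _clamp_floor(vc: VarianceComponents, scales: np.ndarray, floor_rel: float):
    """Clamp tiny/negative diagonals to a small positive floor; returns flags."""
    flags = []
    pos = 0
    for nm, pairs, _ in vc.spec.blocks():
        B = vc.blocks[nm]
        k = len(pairs)
        for i in range(k):
            for j in range(i + 1):
                if i == j:
                    floor = floor_rel * scales[pos]
                    if B[i, i] < floor:
                        B[i, i] = floor
                        flags.append((nm, pairs[i]))
                pos += 1
        # keep correlations inside (-1, 1)
        for i in range(k):
            for j in range(i):
                lim = 0.999 * np.sqrt(B[i, i] * B[j, j])
                if abs(B[i, j]) > lim:
                    B[i, j] = B[j, i] = np.sign(B[i, j]) * lim
    return flags


def _ai_matrix(mm: MixedModel, fac: _Factor) -> np.ndarray:
    """Average-information matrix over the free parameters.

    Working vector for a G-block entry (i, j):  f = Z (D_ij B^-1 kron I) u_hat;
    for a residual entry: f = dR R^-1 e_hat, assembled per record pattern.
    Then AI_kl = f_k' P f_l / 2 with P applied through the factorised MME.
    """
    dm = mm.dm
    F = []
    ehat = fac.residuals()
    Rie = fac.Rinv @ ehat
    for name, pairs, structure in mm.spec.blocks():
        k = len(pairs)
        if structure == "R":
            # per-pattern: f_obs = D[obs,obs] (Rinv e)_obs
            for i in range(k):
                for j in range(i + 1):
                    f = np.zeros(dm.n_obs)
                    for pk, pattern in enumerate(dm.patterns):
                        obs = list(pattern)
                        if i not in obs or j not in obs:
                            continue
                        recs = mm._pattern_records[pk]
                        if recs.size == 0:
                            continue
                        starts = mm._rec_start[recs]
                        oi, oj = obs.index(i), obs.index(j)
                        f[starts + oi] += Rie[starts + oj]
                        if i != j:
                            f[starts + oj] += Rie[starts + oi]
                    F.append(f)
        else:
            B = fac.vc.blocks[name]
            Binv = np.linalg.inv(B)
            U = fac.block_solution(name)  # (k, nl)
            Zb = dm.Z[name]
            for i in range(k):
                for j in range(i + 1):
                    D = np.zeros((k, k))
                    D[i, j] = D[j, i] = 1.0
                    V = (D @ Binv) @ U  # (k, nl)
                    F.append(Zb @ V.ravel())
    F = np.array(F)  # (n_par, n_obs)
    # P f = Rinv f - Rinv W C^-1 W' Rinv f
    RiF = (fac.Rinv @ F.T).T
    WtRiF = (mm.Wcsc.T @ RiF.T).T
    PF = np.empty_like(RiF)
    for k in range(F.shape[0]):
        PF[k] = RiF[k] - fac.Rinv @ (mm.W @ fac.solve(WtRiF[k]))
    AI = 0.5 * (F @ PF.T)
    return 0.5 * (AI + AI.T)


def _takahashi_TQ(mm: MixedModel, fac: _Factor):
    """Per G-block trace and quadratic-form matrices from the selected inverse.

    T[a, b] = tr(K^-1 C^{uu}_{ab})  (selected inverse of the MME matrix)
    Q[a, b] = u_hat_a' K^-1 u_hat_b

    These drive both the exact REML score and the EM update
    B_new = (Q + T) / n_levels.
    """
    mm._ensure_current(fac)
    Zd, Zx = mm._ldl.takahashi()
    if not hasattr(mm, "_tk_lookup"):
        mm._tk_lookup = {}
        for name, pairs, structure in mm.blocks:
            k = len(pairs)
            nl = mm.dm.n_levels[name]
            base = mm.offset[name]
            K = mm.Kinv[name].tocoo()
            look = {}
            for a in range(k):
                for b in range(a + 1):
                    kind, idx = mm._ldl.selected_inverse_lookup(
                        base + a * nl + K.row, base + b * nl + K.col
                    )
                    look[(a, b)] = (kind, idx)
            mm._tk_lookup[name] = (K.data.copy(), look)
    out = {}
    for name, pairs, structure in mm.blocks:
        k = len(pairs)
        nl = mm.dm.n_levels[name]
        Kdata, look = mm._tk_lookup[name]
        U = fac.block_solution(name)
        KU = np.vstack([mm.Kinv[name] @ U[b] for b in range(k)])
        Q = U @ KU.T
        T = np.empty((k, k))
        for a in range(k):
            for b in range(a + 1):
                kind, idx = look[(a, b)]
                # diagonal entries index Zd, off-diagonals Zx
                vals = np.empty(kind.size)
                dmask = kind == 0
                vals[dmask] = Zd[idx[dmask]]
                vals[~dmask] = Zx[idx[~dmask]]
                T[a, b] = T[b, a] = float(Kdata @ vals)
        out[name] = (T, 0.5 * (Q + Q.T), nl)
    return out, (Zd, Zx)


def _exact_gradient(mm: MixedModel, fac: _Factor, TQ, Z):
    """Exact REML score over the free parameters, block by block."""
    Zd, Zx = Z
    grad = []
    dm = mm.dm
    ehat = fac.residuals()
    Rie = fac.Rinv @ ehat
    H = (fac.Rinv @ mm.W).tocsc()
    for name, pairs, structure in mm.spec.blocks():
        k = len(pairs)
        B = fac.vc.blocks[name]
        Binv = np.linalg.inv(B)
        if structure == "R":
            Se = B
            for i in range(k):
                for j in range(i + 1):
                    D = np.zeros((k, k))
                    D[i, j] = D[j, i] = 1.0
                    # dR as sparse over observations
                    rows, cols, vals = [], [], []
                    tr_RinvD = 0.0
                    q = 0.0
                    for pk, pattern in enumerate(dm.patterns):
                        obs = list(pattern)
                        if i not in obs or j not in obs:
                            continue
                        recs = mm._pattern_records[pk]
                        if recs.size == 0:
                            continue
                        starts = mm._rec_start[recs]
                        oi, oj = obs.index(i), obs.index(j)
                        sub = Se[np.ix_(obs, obs)]
                        Einv = np.linalg.inv(sub)
                        Dsub = D[np.ix_(obs, obs)]
                        tr_RinvD += recs.size * float(np.trace(Einv @ Dsub))
                        w = 2.0 if i != j else 1.0
                        q += w * float(np.sum(Rie[starts + oi] * Rie[starts + oj]))
                        rows.append(starts + oi)
                        cols.append(starts + oj)
                        vals.append(np.ones(recs.size))
                        if i != j:
                            rows.append(starts + oj)
                            cols.append(starts + oi)
                            vals.append(np.ones(recs.size))
                    if not rows:
                        grad.append(0.0)
                        continue
                    dR = sp.coo_matrix(
                        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                        shape=(dm.n_obs, dm.n_obs),
                    ).tocsr()
                    Ge = (H.T @ (dR @ H)).tocoo()
                    kind, idx = mm._ldl.selected_inverse_lookup(Ge.row, Ge.col)
                    cv = np.empty(kind.size)
                    dmask = kind == 0
                    cv[dmask] = Zd[idx[dmask]]
                    cv[~dmask] = Zx[idx[~dmask]]
                    trC = float(Ge.data @ cv)
                    grad.append(0.5 * (trC + q - tr_RinvD))
        else:
            T, Q, nl = TQ[name]
            for i in range(k):
                for j in range(i + 1):
                    D = np.zeros((k, k))
                    D[i, j] = D[j, i] = 1.0
                    M = Binv @ D @ Binv
                    g = 0.5 * (float(np.sum(M * (T + Q))) - nl * float(np.trace(Binv @ D)))
                    grad.append(g)
    return np.asarray(grad)


def _em_update(mm: MixedModel, fac: _Factor, TQ) -> VarianceComponents:
    """EM step for the pedigree/dam-structured blocks (residual held fixed)."""
    blocks = {}
    for name, pairs, structure in mm.spec.blocks():
        if structure == "R":
            blocks[name] = fac.vc.blocks[name].copy()
        else:
            T, Q, nl = TQ[name]
            B = (T + Q) / nl
            blocks[name] = 0.5 * (B + B.T)
    return VarianceComponents(
        mm.spec, blocks, n_free_parameters=fac.vc.n_free_parameters
    )


def fit_reml(
    spec: ModelSpec,
    records: pd.DataFrame,
    ped,
    structures: PedigreeStructures | None = None,
    init: VarianceComponents | str = "AUTO",
    tol: float = 1e-8,
    gain_tol: float = 1e-3,
    max_iter: int = 50,
    floor_rel: float = 1e-8,
    verbose: bool = False,
) -> VarianceComponents:
    """Estimate (co)variance components by AI-REML with safeguards.

    Returns a :class:`VarianceComponents` carrying logL, AIC, the AI matrix
    at the optimum and convergence/boundary flags.  Non-convergence within
    ``max_iter`` returns the best iterate flagged, it does not raise.
    """
    if structures is None:
        from .design import pedigree_structures

        structures = pedigree_structures(ped)
    dm = build_design(records, ped, spec, structures)
    mm = MixedModel(dm, structures)
    vc = _auto_init(mm) if isinstance(init, str) else init
    vc.n_free_parameters = spec.n_parameters()
    scales = _param_scales(mm, vc)
    _clamp_floor(vc, scales, floor_rel)

    fac = mm.factor(vc)
    best = fac
    converged = False
    it = 0
    total_it = 0
    meta, diag_of = _param_meta(spec)
    floor_vals = floor_rel * scales
    mu = 1e-8
    for restart in range(3):
        converged = False
        stall = 0
        recent: list = []
        for it in range(1, max_iter + 1):
            TQ, Z = _takahashi_TQ(mm, fac)
            grad = _exact_gradient(mm, fac, TQ, Z)
            AI = _ai_matrix(mm, fac)
            theta = fac.vc.free_vector()

            # active set: variances pinned at the floor with non-positive score
            # are frozen, together with their covariances (held at zero)
            frozen = np.zeros(theta.size, bool)
            for (bidx, i), p in diag_of.items():
                if theta[p] <= floor_vals[p] * 1.01 and grad[p] <= 0.0:
                    frozen[p] = True
            for p, (bidx, i, j) in enumerate(meta):
                if i != j and (frozen[diag_of[(bidx, i)]] or frozen[diag_of[(bidx, j)]]):
                    frozen[p] = True
                    theta[p] = 0.0
            free = ~frozen
            if not free.any():
                converged = True
                break

            # Levenberg-Marquardt step on the free parameters, in scaled
            # coordinates (theta = scale * z) so damping is unit-free; the
            # damping parameter mu persists across iterations
            gs = (grad * scales)[free]
            AIs = (AI * np.outer(scales, scales))[np.ix_(free, free)]
            # predicted gain of a full Newton step; once negligible, more
            # iterations cannot change any model comparison
            try:
                newton_gain = 0.5 * float(
                    gs @ np.linalg.solve(AIs + 1e-12 * np.eye(AIs.shape[0]), gs)
                )
            except np.linalg.LinAlgError:
                newton_gain = np.inf
            if newton_gain < gain_tol:
                converged = True
                break
            improved = False
            capped = False
            cand_fac = fac
            for _ in range(30):
                try:
                    zstep = np.linalg.solve(
                        AIs + mu * np.eye(AIs.shape[0]), gs
                    )
                except np.linalg.LinAlgError:
                    mu = min(max(mu * 10.0, 1e-6), 1e8)
                    continue
                delta = np.zeros_like(theta)
                delta[free] = zstep * scales[free]
                ct = theta + delta
                capped = False
                for (bidx, i), p in diag_of.items():
                    lo = 0.01 * theta[p]
                    if theta[p] > 1.01 * floor_vals[p] and ct[p] < lo:
                        ct[p] = lo
                        capped = True
                cand = fac.vc.with_free_vector(ct)
                _clamp_floor(cand, scales, floor_rel)
                ok = _is_pd(cand)
                if ok:
                    try:
                        cand_fac = mm.factor(cand)
                    except NotPositiveDefinite:
                        ok = False
                if ok and cand_fac.logL >= fac.logL - 1e-12:
                    improved = True
                    # Marquardt gain ratio: actual vs predicted improvement
                    pred = float(gs @ zstep) - 0.5 * float(
                        zstep @ (AIs @ zstep)
                    )
                    rho = (cand_fac.logL - fac.logL) / max(pred, 1e-300)
                    if rho > 0.75:
                        mu = max(mu / 5.0, 1e-10)
                    elif rho < 0.25:
                        mu = min(mu * 3.0, 1e8)
                    break
                if mu >= 1e8:
                    break  # heavy damping still failing: hand over to EM
                mu = min(max(mu * 10.0, 1e-8), 1e8)
            if not improved:
                # EM fallback: guaranteed-ascent step on the pedigree blocks
                em = _em_update(mm, fac, TQ)
                _clamp_floor(em, scales, floor_rel)
                if _is_pd(em):
                    try:
                        em_fac = mm.factor(em)
                        if em_fac.logL > fac.logL:
                            cand_fac = em_fac
                            improved = True
                            mu = 1e-2  # give the Newton step a fresh chance
                    except NotPositiveDefinite:
                        pass
            if not improved:
                converged = True  # no ascent direction left at working precision
                break
            dl = cand_fac.logL - fac.logL
            fac = cand_fac
            if fac.logL > best.logL:
                best = fac
            if verbose:
                gmax = float(np.abs(grad * scales).max())
                print(f"iter {it}: logL={fac.logL:.6f} dlogL={dl:.3e} "
                      f"|g|={gmax:.2e} mu={mu:.1e} frozen={int(frozen.sum())}")
            recent.append(dl)
            plateau = len(recent) >= 5 and sum(recent[-5:]) < 0.05
            stall = stall + 1 if dl < tol else 0
            if (dl < tol and mu <= 1e-6 and not capped) or stall >= 2 or plateau:
                converged = True
                break

        total_it += it
        # EM polish: a premature boundary freeze shows up as an EM step that
        # still improves the likelihood; if so, resume Newton iterations
        fac = best
        TQ, _Zp = _takahashi_TQ(mm, fac)
        em = _em_update(mm, fac, TQ)
        _clamp_floor(em, scales, floor_rel)
        if not _is_pd(em):
            break
        try:
            em_fac = mm.factor(em)
        except NotPositiveDefinite:
            break
        if em_fac.logL > best.logL + 1e-4:
            fac = em_fac
            best = em_fac
            continue
        break


    out = best.vc
    out.spec = spec
    out.logL = best.logL
    out.n_free_parameters = spec.n_parameters()
    out.AIC = aic(out.logL, out.n_free_parameters)
    out.AI_matrix = _ai_matrix(mm, best)
    out.n_iter = total_it
    out.boundary_flags = _clamp_floor(out, scales, floor_rel * 1.01)
    out.converged = converged
    out._mixed_model = mm
    return out


# ---------------------------------------------------------------------------
# model selection and derived parameters


def select_model(
    candidates: list[ModelSpec], records, ped, structures=None, **fit_kw
) -> pd.DataFrame:
    """Fit every candidate and rank by AIC (ties: fewer parameters, input order)."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    rows = []
    fits = []
    for k, spec in enumerate(candidates):
        vc = fit_reml(spec, records, ped, structures=structures, **fit_kw)
        fits.append(vc)
        rows.append(
            dict(model=spec.name, logL=vc.logL, P=vc.n_free_parameters,
                 AIC=vc.AIC, converged=vc.converged, order=k)
        )
    out = pd.DataFrame(rows).sort_values(["AIC", "P", "order"]).reset_index(drop=True)
    out["dAIC"] = out["AIC"] - out["AIC"].iloc[0]
    out.attrs["fits"] = {f.spec.name: f for f in fits}
    return out.drop(columns="order")


@dataclass
class GeneticParameters:
    table: pd.DataFrame  # per-trait ratios with SEs
    r_a: pd.DataFrame | None
    r_s: pd.DataFrame | None
    sexlinked_share: pd.Series


def _free_index(vc: VarianceComponents, term: str, trait_x: str, trait_y: str) -> int:
    pos = 0
    look = term
    for nm, pairs, _ in vc.spec.blocks():
        k = len(pairs)
        for i in range(k):
            for j in range(i + 1):
                a, b = pairs[i], pairs[j]
                if {a, b} == {(look, trait_x), (look, trait_y)} or (
                    trait_x == trait_y and a == b == (look, trait_x)
                ):
                    return pos
                pos += 1
    return -1


def genetic_parameters(vc: VarianceComponents) -> GeneticParameters:
    """Heritabilities, variance ratios and genetic correlations with SEs.

    The phenotypic variance of a trait is the plain sum of its fitted
    variance components (X-linked variance counted once, at its
    base-female scale) plus the direct-maternal covariance when modeled.
    Standard errors come from the delta method on the inverse AI matrix.
    """
    spec = vc.spec
    traits = list(spec.traits)
    cov = None
    if vc.AI_matrix is not None:
        AIr = vc.AI_matrix + 1e-12 * np.eye(vc.AI_matrix.shape[0])
        cov = np.linalg.pinv(AIr)
    theta = vc.free_vector()

    def sigma_terms(trait):
        terms = [(term, _free_index(vc, term, trait, trait))
                 for term in list(spec.random_terms) + ["R"]]
        terms = [(t, i) for t, i in terms if i >= 0]
        if spec.direct_maternal_covariance:
            pos = _am_cross_index(vc, trait)
            if pos >= 0:
                terms.append(("am_cov", pos))
        return terms

    def _am_cross_index(vc, trait):
        pos = 0
        for nm, pairs, _ in vc.spec.blocks():
            k = len(pairs)
            for i in range(k):
                for j in range(i + 1):
                    if {pairs[i], pairs[j]} == {(AAG, trait), (MGE, trait)}:
                        return pos
                    pos += 1
        return -1

    rows = []
    for trait in traits:
        terms = sigma_terms(trait)
        idx = [i for _, i in terms]
        sigmaP = float(np.sum(theta[idx]))
        row = dict(trait=trait, sigma_P=sigmaP)
        ratio_of = {AAG: "h2_a", "SLAG": "h2_s", MGE: "h2_m", "MPE": "pe2"}
        for term, i in terms:
            if term not in ratio_of:
                continue
            name = ratio_of[term]
            val = theta[i] / sigmaP
            row[name] = val
            if cov is not None:
                # delta method: ratio = x_i / sum(x_idx)
                g = np.zeros(theta.size)
                for j in idx:
                    g[j] = -theta[i] / sigmaP**2
                g[i] += 1.0 / sigmaP
                row[name + "_se"] = float(np.sqrt(max(g @ cov @ g, 0.0)))
        # direct-maternal correlation
        if spec.direct_maternal_covariance:
            sa = vc.get(AAG, trait)
            sm = vc.get(MGE, trait)
            sam = vc.direct_maternal_cov(trait)
            if sa > 0 and sm > 0:
                row["r_am"] = sam / np.sqrt(sa * sm)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("trait")

    def corr_frame(term):
        trs = [t for t in traits if t in spec.random_terms.get(term, ())]
        if len(trs) < 2:
            return None
        M = pd.DataFrame(np.eye(len(trs)), index=trs, columns=trs)
        for i, tx in enumerate(trs):
            for j, ty in enumerate(trs):
                if i < j:
                    vx, vy = vc.get(term, tx), vc.get(term, ty)
                    cxy = vc.get(term, tx, ty)
                    r = cxy / np.sqrt(vx * vy) if vx > 0 and vy > 0 else np.nan
                    M.iloc[i, j] = M.iloc[j, i] = r
        return M

    r_a = corr_frame(AAG)
    r_s = corr_frame("SLAG")
    share = {}
    for trait in traits:
        sa = vc.get(AAG, trait)
        ss = vc.get("SLAG", trait)
        share[trait] = 100.0 * ss / (sa + ss) if (sa + ss) > 0 else np.nan
    return GeneticParameters(table, r_a, r_s, pd.Series(share, name="sexlinked_share_pct"))


def genetic_correlations(Sigma_x: np.ndarray, labels=None) -> np.ndarray:
    """Correlation matrix from a covariance block; negative diagonals raise."""
    d = np.diag(Sigma_x).astype(float)
    if np.any(d < 0):
        raise ValueError("negative variance on the diagonal")
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(d, d))
        R = np.where(denom > 0, Sigma_x / denom, np.nan)
    np.fill_diagonal(R, np.where(d > 0, 1.0, np.nan))
    return R
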