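"""Design matrices linking phenotype records to an animal-model structure.

Observations are stacked record-major: for each phenotype record, one row
per observed trait.  The residual is block-diagonal over records, with each
record's block the residual covariance restricted to its observed traits —
this is how unbalanced trait patterns (far more birth-weight than weaning
records) enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .models import TERM_CARRIER, ModelSpec
from .pedigree import Pedigree, inbreeding
from .kinship import build_A_inverse, build_S_inverse, logdet_A, logdet_S, xlinked_inbreeding


@dataclass
class PedigreeStructures:
    """Sparse inverse relationship structures shared by all model fits."""

    ped: Pedigree
    A_inv: sp.csr_matrix
    S_inv: sp.csr_matrix | None
    logdet_A: float
    logdet_S: float

    def inv(self, structure: str, n_levels: int):
        if structure == "A":
            return self.A_inv, self.logdet_A
        if structure == "S":
            if self.S_inv is None:
                raise ValueError("pedigree structures built without S")
            return self.S_inv, self.logdet_S
        return sp.eye(n_levels, format="csr"), 0.0


def pedigree_structures(ped: Pedigree, with_S: bool = True) -> PedigreeStructures:
    F = inbreeding(ped)
    A_inv = build_A_inverse(ped, F)
    ldA = logdet_A(ped, F)
    S_inv = None
    ldS = 0.0
    if with_S:
        Fx = xlinked_inbreeding(ped)
        S_inv = build_S_inverse(ped, Fx)
        ldS = logdet_S(ped, Fx)
    return PedigreeStructures(ped, A_inv, S_inv, ldA, ldS)


@dataclass
class DesignMatrices:
    spec: ModelSpec
    y: np.ndarray
    X: sp.csr_matrix
    x_labels: list
    Z: dict  # block name -> csr, columns = pairs-major over levels
    n_levels: dict  # block name -> number of levels per (term, trait) pair
    level_ids: dict  # block name -> id array of the levels
    obs_record: np.ndarray  # record index per observation row
    obs_trait: np.ndarray  # trait index (within spec.traits) per observation row
    patterns: list  # distinct observed-trait tuples
    pattern_of_record: np.ndarray  # pattern index per record
    records: pd.DataFrame
    excluded: pd.DataFrame
    trait_scale: np.ndarray = field(default=None)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_records(self) -> int:
        return len(self.records)


def _fixed_design(records: pd.DataFrame, factors: list, trait: str):
    """Intercept + treatment-coded dummies; aliased columns dropped by QR."""
    cols = [np.ones(len(records))]
    labels = [f"{trait}:intercept"]
    for f in factors:
        v = records[f]
        levels = sorted(pd.unique(v.astype(str)))
        for lv in levels[1:]:
            cols.append((v.astype(str) == lv).to_numpy(float))
            labels.append(f"{trait}:{f}={lv}")
    Xt = np.column_stack(cols)
    # drop linearly dependent columns deterministically (last-listed first)
    keep = np.ones(Xt.shape[1], bool)
    while keep.any():
        r = np.linalg.qr(Xt[:, keep], mode="r")
        d = np.abs(np.diag(r))
        bad = np.where(d < 1e-8 * max(d.max(), 1.0))[0]
        if bad.size == 0:
            break
        keep[np.where(keep)[0][bad[-1]]] = False
    dropped = [l for l, k in zip(labels, keep) if not k]
    return Xt[:, keep], [l for l, k in zip(labels, keep) if k], dropped


def build_design(
    records: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    structures: PedigreeStructures | None = None,
) -> DesignMatrices:
    """Assemble y, X and the random-effect incidences for a model structure.

    Records whose animal is missing from the pedigree raise; records with an
    unknown dam are excluded (with a log entry) whenever the model carries a
    maternal term.  A record contributes one observation row per non-missing
    trait.
    """
    traits = list(spec.traits)
    rec = records.reset_index(drop=True).copy()

    known = set(ped.df["animal"])
    missing_anim = [a for a in rec["animal_id"] if a not in known]
    if missing_anim:
        raise ValueError(f"record animals missing from pedigree: {missing_anim[:5]}")

    needs_dam = any(TERM_CARRIER[t] == "dam" for t in spec.random_terms)
    excl_mask = np.zeros(len(rec), bool)
    reasons = np.array([""] * len(rec), object)
    if needs_dam:
        bad = rec["dam_id"].isna() | ~rec["dam_id"].isin(set(ped.df["animal"]))
        excl_mask |= bad.to_numpy()
        reasons[bad.to_numpy()] = "unknown dam under a maternal term"
    fixed_cols = sorted({f for fl in spec.fixed_effects.values() for f in fl})
    for f in fixed_cols:
        bad = rec[f].isna().to_numpy()
        excl_mask |= bad
        reasons[bad] = np.where(reasons[bad] == "", f"missing fixed effect {f}", reasons[bad])
    has_any = rec[traits].notna().any(axis=1).to_numpy()
    excl_mask |= ~has_any
    reasons[~has_any] = "no observed trait"
    excluded = rec.loc[excl_mask].copy()
    excluded["reason"] = reasons[excl_mask]
    rec = rec.loc[~excl_mask].reset_index(drop=True)

    # observation stacking
    obs_record, obs_trait, yv = [], [], []
    pat_of_rec = np.empty(len(rec), np.int64)
    patterns: list[tuple] = []
    pat_index: dict[tuple, int] = {}
    tvals = rec[traits].to_numpy(float)
    for r in range(len(rec)):
        obs = tuple(np.where(~np.isnan(tvals[r]))[0])
        k = pat_index.setdefault(obs, len(patterns))
        if k == len(patterns):
            patterns.append(obs)
        pat_of_rec[r] = k
        for t in obs:
            obs_record.append(r)
            obs_trait.append(t)
            yv.append(tvals[r, t])
    obs_record = np.array(obs_record)
    obs_trait = np.array(obs_trait)
    y = np.array(yv)
    n_obs = y.size

    # fixed design, block per trait
    Xparts, labels = [], []
    for t, trait in enumerate(traits):
        rows = np.where(obs_trait == t)[0]
        sub = rec.iloc[obs_record[rows]]
        Xt, lab, dropped = _fixed_design(sub, spec.fixed_effects.get(trait, []), trait)
        M = sp.lil_matrix((n_obs, Xt.shape[1]))
        M[rows, :] = Xt
        Xparts.append(M.tocsr())
        labels.extend(lab)
    X = sp.hstack(Xparts, format="csr")

    # random incidences
    anim_pos = np.array([ped.position(a) for a in rec["animal_id"]])
    dam_pos = np.full(len(rec), -1)
    if needs_dam:
        dam_pos = np.array([ped.position(d) for d in rec["dam_id"]])
    n_ped = len(ped)
    Z, n_levels, level_ids = {}, {}, {}
    for name, pairs, structure in spec.blocks():
        if structure == "R":
            continue
        if structure == "I_dam":
            uniq = np.unique(dam_pos[dam_pos >= 0])
            lvl_of = {p: k for k, p in enumerate(uniq)}
            nl = len(uniq)
            level_ids[name] = ped.animals[uniq]
        else:
            nl = n_ped
            level_ids[name] = ped.animals
        rows_, cols_ = [], []
        for j, (term, trait) in enumerate(pairs):
            t = traits.index(trait)
            orows = np.where(obs_trait == t)[0]
            carrier = TERM_CARRIER[term]
            for o in orows:
                r = obs_record[o]
                p = anim_pos[r] if carrier == "animal" else dam_pos[r]
                if structure == "I_dam":
                    p = lvl_of[p]
                rows_.append(o)
                cols_.append(j * nl + p)
        Z[name] = sp.coo_matrix(
            (np.ones(len(rows_)), (rows_, cols_)), shape=(n_obs, len(pairs) * nl)
        ).tocsr()
        n_levels[name] = nl

    scale = np.array([np.nanvar(tvals[:, t]) for t in range(len(traits))])
    return DesignMatrices(
        spec=spec, y=y, X=X, x_labels=labels, Z=Z, n_levels=n_levels,
        level_ids=level_ids, obs_record=obs_record, obs_trait=obs_trait,
        patterns=patterns, pattern_of_record=pat_of_rec, records=rec,
        excluded=excluded, trait_scale=scale,
    )
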