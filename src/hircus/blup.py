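"""Breeding-value prediction (BLUP) and genetic-trend regression.

At converged (or supplied) variance components, Henderson's mixed-model
equations are solved by sparse factorisation; every pedigree animal gets a
predicted autosomal (a_hat) and X-linked (s_hat) breeding value per trait,
plus a maternal value (m_hat) when the model carries one.  Genetic trends
are ordinary least-squares regressions of predicted breeding values on
birth date expressed in fractional years (365.25-day years), one slope per
trait and component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PedigreeStructures, build_design
from .models import ModelSpec, VarianceComponents
from .pedigree import Pedigree
from .reml import MixedModel


@dataclass
class EBVTable:
    """Predicted breeding values for every pedigree animal.

    ``frame`` columns: animal_id, birth_date, then one column per
    (component, trait) pair named like ``a_BWT``, ``s_BWT``, ``m_BWT``.
    """

    frame: pd.DataFrame
    fixed_effects: pd.Series
    converged: bool
    mme_residual: float

    def component(self, component: str, trait: str) -> pd.Series:
        return self.frame[f"{component}_{trait}"]

    def to_csv(self, path) -> None:
        long = self.frame.melt(
            id_vars=["animal_id", "birth_date"], var_name="effect", value_name="value"
        )
        long[["component", "trait"]] = long["effect"].str.split("_", n=1, expand=True)
        long.drop(columns="effect").to_csv(path, index=False)


@dataclass
class GeneticTrend:
    trait: str
    component: str
    b1: float
    b0: float
    SE_b1: float
    n_animals: int


_COMPONENT_OF_TERM = {"AAG": "a", "SLAG": "s", "MGE": "m", "MPE": "pe"}


def solve_mme(
    vc: VarianceComponents,
    records: pd.DataFrame,
    ped: Pedigree,
    structures: PedigreeStructures | None = None,
    mm: MixedModel | None = None,
) -> EBVTable:
    """Solve the mixed-model equations at given variance components.

    Reuses the fitted model's assembled equations when available (fit_reml
    attaches them to its result); otherwise builds them from the inputs.
    """
    if mm is None:
        mm = getattr(vc, "_mixed_model", None)
    if mm is None:
        if structures is None:
            from .design import pedigree_structures

            structures = pedigree_structures(ped)
        dm = build_design(records, ped, vc.spec, structures)
        mm = MixedModel(dm, structures)
    fac = mm.factor(vc)
    # relative residual of the solved system
    C = mm._current_C
    rhs = fac.rhs
    res = float(np.abs(C @ fac.sol - rhs).max() / max(np.abs(rhs).max(), 1.0))

    df = ped.df
    out = pd.DataFrame(
        {"animal_id": df["animal"].to_numpy(), "birth_date": df["birth_date"].to_numpy()}
    )
    for name, pairs, structure in vc.spec.blocks():
        if structure == "R":
            continue
        U = fac.block_solution(name)
        for j, (term, trait) in enumerate(pairs):
            comp = _COMPONENT_OF_TERM[term]
            if structure == "I_dam":
                col = np.full(len(df), np.nan)
                pos = {a: i for i, a in enumerate(df["animal"])}
                for k, aid in enumerate(mm.dm.level_ids[name]):
                    col[pos[aid]] = U[j, k]
            else:
                col = U[j]
            out[f"{comp}_{trait}"] = col
    fixed = pd.Series(fac.fixed_solution(), index=mm.dm.x_labels)
    return EBVTable(out, fixed, bool(getattr(vc, "converged", True)), res)


def fractional_year(dates: pd.Series) -> np.ndarray:
    """Calendar date -> year + day_of_year / 365.25."""
    d = pd.to_datetime(dates)
    return (d.dt.year + (d.dt.dayofyear - 1) / 365.25).to_numpy(float)


def genetic_trend(
    ebv: EBVTable | pd.DataFrame, component: str, trait: str
) -> GeneticTrend:
    """OLS slope of predicted breeding values on fractional birth year."""
    frame = ebv.frame if isinstance(ebv, EBVTable) else ebv
    comp = {"autosomal": "a", "xlinked": "s", "maternal": "m"}.get(component, component)
    col = f"{comp}_{trait}"
    sub = frame[["birth_date", col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three animals with birth dates")
    x = fractional_year(sub["birth_date"])
    if np.ptp(x) == 0:
        raise ValueError("all birth dates identical; slope undefined")
    y = sub[col].to_numpy(float)
    xm = x - x.mean()
    b1 = float(xm @ (y - y.mean()) / (xm @ xm))
    b0 = float(y.mean() - b1 * x.mean())
    resid = y - (b0 + b1 * x)
    dof = len(y) - 2
    se = float(np.sqrt(resid @ resid / dof / (xm @ xm)))
    return GeneticTrend(trait, component, b1, b0, se, len(y))


def trend_table(ebv: EBVTable, traits, components=("autosomal", "xlinked")) -> pd.DataFrame:
    rows = []
    for comp in components:
        for t in traits:
            col = {"autosomal": "a", "xlinked": "s", "maternal": "m"}[comp] + f"_{t}"
            if col not in ebv.frame:
                continue
            tr = genetic_trend(ebv, comp, t)
            rows.append(
                dict(trait=t, component=comp, slope_per_year=tr.b1,
                     SE=tr.SE_b1, intercept=tr.b0, n=tr.n_animals)
            )
    return pd.DataFrame(rows)
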