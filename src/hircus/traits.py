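"""Growth-trait derivation, quality control and fixed-effect screening.

From raw birth weight (BWT, kg), weaning weight (WWT, kg) and weaning age
(days) three derived pre-weaning traits are computed:

* PWGR — growth rate, (WWT - BWT) / weaning_age * 1000, in g/day;
* PWKR — Kleiber ratio, PWGR / WWT^0.75, growth per unit metabolic weight;
* PWGE — growth efficiency, (WWT - BWT) / BWT * 100, in percent.

Quality control removes records outside mean +/- k standard deviations
(single pass, k = 3 by default), and distributional health is reported via
skewness and kurtosis (kurtosis on the normal = 3 scale).  Fixed effects
(birth year, birth month, sex, birth type, dam age, parity) are screened
with marginal F-tests from an all-factor least-squares model; factors with
p < 0.05 are flagged for inclusion in the animal models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DERIVED_TRAITS = ("PWGR", "PWKR", "PWGE")


@dataclass
class TraitSummary:
    n_records: int
    n_animals: int
    mean: float
    SD: float
    CV_percent: float
    min: float
    max: float
    skewness: float
    kurtosis: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def derive_traits(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append PWGR, PWKR, PWGE columns; records lacking WWT or weaning age
    are passed through with the derived traits missing (and logged).

    Returns (records_with_derived, skip_log).
    """
    rec = records.copy()
    if (rec["BWT"] <= 0).any():
        bad = rec.loc[rec["BWT"] <= 0, "animal_id"].tolist()[:5]
        raise ValueError(f"non-positive birth weight for {bad}")
    ok = rec["WWT"].notna() & rec["weaning_age"].notna()
    if (rec.loc[ok, "weaning_age"] <= 0).any():
        raise ValueError("non-positive weaning age")
    gain = rec.loc[ok, "WWT"] - rec.loc[ok, "BWT"]
    rec.loc[ok, "PWGR"] = gain / rec.loc[ok, "weaning_age"] * 1000.0
    rec.loc[ok, "PWKR"] = rec.loc[ok, "PWGR"] / rec.loc[ok, "WWT"] ** 0.75
    rec.loc[ok, "PWGE"] = gain / rec.loc[ok, "BWT"] * 100.0
    for t in DERIVED_TRAITS:
        if t not in rec:
            rec[t] = np.nan
    skipped = rec.loc[~ok, ["animal_id"]].copy()
    skipped["reason"] = np.where(
        records.loc[~ok, "WWT"].isna(), "missing WWT", "missing weaning age"
    )
    return rec, skipped


def filter_outliers(values: pd.Series, k: float = 3.0):
    """Single-pass mean +/- k*SD filter (closed interval: boundary kept).

    Mean and SD come from the input as given and are not re-estimated after
    removal.  Returns (kept, removal_log).
    """
    v = values.dropna()
    if len(v) < 2:
        raise ValueError("need at least two records")
    m, s = v.mean(), v.std(ddof=1)
    if s == 0:
        return values, pd.DataFrame(columns=["id", "value"])
    lo, hi = m - k * s, m + k * s
    out = (v < lo) | (v > hi)
    removed = pd.DataFrame({"id": v.index[out], "value": v[out].to_numpy()})
    kept = values.copy()
    kept[v.index[out]] = np.nan
    return kept, removed


def summarize_trait(values: pd.Series, ids: pd.Series | None = None) -> TraitSummary:
    """Descriptive statistics with sample SD and normal-=3 kurtosis."""
    v = values.dropna().to_numpy(float)
    if v.size < 2:
        raise ValueError("need at least two records")
    m = v.mean()
    s = v.std(ddof=1)
    z = (v - m) / s if s > 0 else np.zeros_like(v)
    n_animals = int(ids.loc[values.notna()].nunique()) if ids is not None else v.size
    return TraitSummary(
        n_records=int(v.size),
        n_animals=n_animals,
        mean=float(m),
        SD=float(s),
        CV_percent=float(s / m * 100.0) if m != 0 else np.nan,
        min=float(v.min()),
        max=float(v.max()),
        skewness=float(np.mean(z**3)),
        kurtosis=float(np.mean(z**4)),
    )


def summary_table(records: pd.DataFrame, traits, id_col: str = "animal_id") -> pd.DataFrame:
    rows = {}
    for t in traits:
        rows[t] = summarize_trait(records[t], records[id_col]).to_series()
    return pd.DataFrame(rows)


def data_structure_table(records: pd.DataFrame, traits) -> pd.DataFrame:
    """Per-trait data-structure characteristics: record and parent counts,
    records per sire/dam, and the descriptive moments."""
    rows = {}
    for t in traits:
        sub = records.loc[records[t].notna()]
        n = len(sub)
        n_sires = sub["sire_id"].nunique() if "sire_id" in sub else np.nan
        n_dams = sub["dam_id"].nunique() if "dam_id" in sub else np.nan
        s = summarize_trait(sub[t], sub.get("animal_id")).to_series()
        s["n_sires"] = n_sires
        s["n_dams"] = n_dams
        s["records_per_sire"] = n / n_sires if n_sires else np.nan
        s["records_per_dam"] = n / n_dams if n_dams else np.nan
        rows[t] = s
    return pd.DataFrame(rows)


def screen_fixed_effects(
    records: pd.DataFrame,
    factors: list,
    trait: str,
    alpha: float = 0.05,
) -> dict:
    """Marginal F-tests and least-squares means for an all-factor model.

    Fits ``trait ~ C(f1) + C(f2) + ...`` by OLS and reports per-factor
    marginal (order-invariant) F-tests; factors with p < alpha are flagged
    for inclusion in the animal model.  LS means are model predictions per
    level averaged over a balanced grid of the other factors.

    Returns {"anova": DataFrame, "ls_means": DataFrame, "significant": list}.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    use = records[[trait] + list(factors)].dropna()
    for f in factors:
        if use[f].nunique() < 2:
            raise ValueError(f"factor {f} has fewer than two levels")
    formula = f"{trait} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=use).fit()
    anova = anova_lm(fit, typ=2)
    anova = anova.rename(index=lambda s: s.replace("C(", "").replace(")", ""))
    pvals = anova["PR(>F)"].drop("Residual", errors="ignore")
    significant = [f for f in factors if pvals.get(f, 1.0) < alpha]

    # LS means over a balanced grid of the other factors
    ls_rows = []
    levels = {f: sorted(use[f].unique()) for f in factors}
    for f in factors:
        others = [g for g in factors if g != f]
        import itertools

        grid_other = list(itertools.product(*[levels[g] for g in others])) or [()]
        for lv in levels[f]:
            grid = pd.DataFrame(
                [dict({f: lv}, **dict(zip(others, combo))) for combo in grid_other]
            )
            design = fit.model.data.design_info
            from patsy import dmatrix

            X = np.asarray(dmatrix(design, grid, return_type="matrix"))
            w = X.mean(axis=0)
            est = float(w @ fit.params)
            se = float(np.sqrt(w @ fit.cov_params() @ w))
            ls_rows.append(dict(factor=f, level=lv, ls_mean=est, se=se))
    ls_means = pd.DataFrame(ls_rows)
    return {"anova": anova, "ls_means": ls_means, "significant": significant}
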