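"""Synthetic goat-herd generator.

Emulates a closed dairy-goat herd under an intensive mating system: discrete
generations, a fixed mating ratio of does per buck, litters of one to three
kids, birth dates spread over an eight-year span, and phenotypes generated
from the same animal model the estimation machinery assumes — autosomal (a),
X-linked (s), maternal genetic (m), maternal permanent environmental (pe)
and residual (e) effects:

    y_trait = mu + fixed effects + a + s + m_dam + pe_dam + e

a and m follow the usual parent-average recursion with pedigree-correct
Mendelian sampling variances; s descends gamete by gamete (a sire passes
his whole X to every daughter and nothing to sons), matching the S-matrix
convention of :mod:`hircus.kinship` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree, sort_topological
from .kinship import xlinked_inbreeding
from .pedigree import inbreeding


def _sym(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    return 0.5 * (a + a.T)


@dataclass
class SimulationScenario:
    """Frozen description of a simulated herd and its generative parameters.

    Variance blocks are over the base traits (default BWT, WWT in kg).
    ``sigma_am`` is the optional direct-maternal genetic cross-covariance
    (zero by default).  ``wwt_missing_fraction`` is the share of kids with
    no weaning record, mimicking the attrition between birth and weaning.
    """

    traits: tuple = ("BWT", "WWT")
    n_generations: int = 4
    n_dams_per_generation: int = 850
    does_per_buck: int = 15
    litter_probs: dict = field(default_factory=lambda: {1: 0.5, 2: 0.45, 3: 0.05})
    birth_year_start: int = 2016
    birth_year_span: int = 8
    weaning_age_mean: float = 80.0
    weaning_age_sd: float = 5.0
    wwt_missing_fraction: float = 0.53
    mu: dict = field(default_factory=lambda: {"BWT": 2.58, "WWT": 10.58})
    # fixed-effect sizes, per trait
    sex_effect: dict = field(default_factory=lambda: {"BWT": 0.11, "WWT": 0.235})
    year_effect_amplitude: dict = field(default_factory=lambda: {"BWT": 0.08, "WWT": 0.20})
    month_effect_amplitude: dict = field(default_factory=lambda: {"BWT": 0.05, "WWT": 0.15})
    birth_type_effect: dict = field(
        default_factory=lambda: {"BWT": (0.11, 0.0, -0.16), "WWT": (0.07, 0.0, -0.24)}
    )
    dam_age_slope: dict = field(default_factory=lambda: {"BWT": 0.04, "WWT": 0.08})
    parity_slope: dict = field(default_factory=lambda: {"BWT": 0.02, "WWT": 0.05})
    # (co)variance blocks, trait x trait
    Sigma_a: np.ndarray = field(
        default_factory=lambda: _cov([0.007, 0.126], 0.13)
    )
    Sigma_s: np.ndarray = field(
        default_factory=lambda: _cov([0.004, 0.036], -0.5)
    )
    Sigma_m: np.ndarray = field(
        default_factory=lambda: _cov([0.018, 0.061], 0.5)
    )
    Sigma_pe: np.ndarray = field(default_factory=lambda: np.array([[0.001]]))
    pe_traits: tuple = ("BWT",)
    Sigma_e: np.ndarray = field(
        default_factory=lambda: _cov([0.108, 1.430], 0.3)
    )
    sigma_am: np.ndarray | None = None
    selection: tuple | None = None  # e.g. ("phenotype", "WWT") or ("true_a", "WWT")
    seed: int = 20160101

    def __post_init__(self) -> None:
        for name in ("Sigma_a", "Sigma_s", "Sigma_m", "Sigma_pe", "Sigma_e"):
            m = _sym(getattr(self, name))
            setattr(self, name, m)
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
        p = sum(self.litter_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError("litter-size probabilities must sum to 1")
        if self.does_per_buck < 1:
            raise ValueError("does_per_buck must be >= 1")

    @property
    def n_sires_per_generation(self) -> int:
        return int(np.ceil(self.n_dams_per_generation / self.does_per_buck))

    def describe(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def _cov(variances, corr) -> np.ndarray:
    v = np.asarray(variances, dtype=float)
    sd = np.sqrt(v)
    c = np.full((len(v), len(v)), corr, dtype=float)
    np.fill_diagonal(c, 1.0)
    return c * np.outer(sd, sd)



def _safe_chol(M: np.ndarray) -> np.ndarray:
    """Cholesky factor that tolerates PSD (including zero) matrices."""
    M = np.asarray(M, float)
    if not M.size or np.allclose(M, 0.0):
        return np.zeros_like(M)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(np.trace(M) / max(M.shape[0], 1), 1e-30)
        return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))


def default_scenario() -> SimulationScenario:
    """The frozen default: a herd whose BWT/WWT variance architecture uses
    the best-supported multivariate structure (a + s + m + pe-on-BWT + e)."""
    return SimulationScenario()


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(sc: SimulationScenario, seed: int | None = None) -> Pedigree:
    """Discrete-generation herd pedigree with seasonal birth dates.

    Founders form generation 0.  Each later generation mates
    ``n_dams_per_generation`` does (drawn from the previous two cohorts, so
    parity and dam age vary) to bucks at the configured mating ratio.
    Returns a topologically sorted, validated pedigree; kid metadata
    (birth type, dam age, parity) travels in extra columns.
    """
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    n_sires = sc.n_sires_per_generation
    n_dams = sc.n_dams_per_generation
    if n_sires > n_dams:
        raise ValueError("more sires than dams; infeasible mating plan")
    years_per_gen = max(1, sc.birth_year_span // sc.n_generations)

    rows: list[dict] = []
    nid = 0

    def new_animal(sex, sire, dam, year, month, day, **extra):
        nonlocal nid
        aid = f"G{nid:06d}"
        nid += 1
        rows.append(
            dict(animal=aid, sire=sire, dam=dam, sex=sex,
                 birth_date=pd.Timestamp(year=year, month=month, day=day), **extra)
        )
        return aid

    y0 = sc.birth_year_start
    founder_sires = [
        new_animal(MALE, None, None, y0 - 2, int(rng.integers(1, 13)), int(rng.integers(1, 29)),
                   birth_type=0, dam_age=0, parity=0, generation=0)
        for _ in range(n_sires)
    ]
    founder_dams = [
        new_animal(FEMALE, None, None, y0 - int(rng.integers(2, 4)),
                   int(rng.integers(1, 13)), int(rng.integers(1, 29)),
                   birth_type=0, dam_age=0, parity=0, generation=0)
        for _ in range(n_dams)
    ]

    litter_sizes = np.array(sorted(sc.litter_probs))
    litter_p = np.array([sc.litter_probs[k] for k in litter_sizes])
    # months weighted toward late winter / spring kidding
    month_p = np.array([2, 3, 3, 2.5, 1.5, 1, 0.5, 0.5, 0.5, 0.5, 1, 1.5])
    month_p = month_p / month_p.sum()

    birth_year = {r["animal"]: r["birth_date"].year for r in rows}
    parity_count: dict[str, int] = {}
    sire_pool = list(founder_sires)
    dam_pool = [(d, 1.0) for d in founder_dams]

    # heritable merit score for optional truncation selection: standardized
    # additive value following the parent-average recursion.  Stored in the
    # output so breeding-value simulation can reuse it as the selected
    # trait's additive component (keeping data and selection consistent).
    merit: dict[str, float] = {}
    select_on = sc.selection  # None | ("phenotype"|"true_a", trait)
    for r in rows:
        merit[r["animal"]] = float(rng.standard_normal())

    def kid_merit(s, d):
        return 0.5 * (merit[s] + merit[d]) + np.sqrt(0.5) * rng.standard_normal()

    def rank_key(aid):
        if select_on is None:
            return 0.0
        if select_on[0] == "phenotype":
            # phenotype on the standardized scale: additive merit plus
            # environmental noise sized so merit explains ~1/3 of variance
            return merit[aid] + np.sqrt(2.0) * rng.standard_normal()
        return merit[aid]

    for gen in range(1, sc.n_generations + 1):
        gen_year = y0 + (gen - 1) * years_per_gen
        # dams: prefer younger candidates; selection rule may rank them
        candidates = [d for d, _ in dam_pool]
        if len(candidates) < n_dams:
            raise ValueError("not enough does available for the mating plan")
        dams = candidates[:n_dams]
        sires = sire_pool[:n_sires]
        # ~does_per_buck does per buck: contiguous blocks after shuffling
        dams = list(rng.permutation(dams))
        mate_of = {}
        for k, d in enumerate(dams):
            mate_of[d] = sires[k % n_sires]

        cohort = []
        for d in dams:
            s = mate_of[d]
            parity_count[d] = parity_count.get(d, 0) + 1
            year = gen_year + int(rng.integers(0, years_per_gen))
            year = min(year, y0 + sc.birth_year_span - 1)
            month = int(rng.choice(np.arange(1, 13), p=month_p))
            day = int(rng.integers(1, 29))
            nkids = int(rng.choice(litter_sizes, p=litter_p))
            dam_age = max(1, year - birth_year[d])
            for _ in range(nkids):
                sex = MALE if rng.random() < 0.5 else FEMALE
                aid = new_animal(
                    sex, s, d, year, month, day,
                    birth_type=nkids, dam_age=dam_age, parity=parity_count[d],
                    generation=gen,
                )
                birth_year[aid] = year
                merit[aid] = kid_merit(s, d)
                cohort.append(aid)

        # next-generation parents: males from this cohort, does from the two
        # youngest cohorts so parity and dam age vary
        males = [a for a in cohort if rows[int(a[1:])]["sex"] == MALE]
        females = [a for a in cohort if rows[int(a[1:])]["sex"] == FEMALE]
        if sc.selection is not None:
            males = sorted(males, key=lambda a: -rank_key(a))
            females = sorted(females, key=lambda a: -rank_key(a))
        else:
            males = list(rng.permutation(males))
            females = list(rng.permutation(females))
        sire_pool = males
        carry = [d for d, _ in dam_pool if parity_count.get(d, 0) < 2]
        carry = [d for d in carry if birth_year[d] >= gen_year - 2 * years_per_gen]
        dam_pool = [(f, 0.0) for f in females] + [(d, 1.0) for d in carry]

    df = pd.DataFrame(rows)
    df["sel_merit"] = df["animal"].map(merit)
    ped = Pedigree(df)  # canonical five columns plus kid metadata
    ped.validated = True
    out = sort_topological(ped)
    out.validated = True
    return out


# ---------------------------------------------------------------------------
# breeding values


def simulate_breeding_values(
    ped: Pedigree, sc: SimulationScenario, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Sample a (autosomal), s (X-linked) and m (maternal) effect vectors.

    Returns arrays of shape (n_animals, n_traits) aligned with the sorted
    pedigree.  a and m are drawn jointly from the parent-average recursion
    with cross-covariance ``sigma_am`` (zero by default); s descends by
    explicit gametes so that Cov(s) = Sigma_s kron-structured by S.
    """
    rng = np.random.default_rng((sc.seed + 1) if seed is None else seed)
    nt = len(sc.traits)
    sire, dam = ped.parent_indices()
    sex = ped.sex_codes
    n = len(ped)
    F = inbreeding(ped)

    # joint (a, m): 2*nt per animal
    Sam = sc.sigma_am if sc.sigma_am is not None else np.zeros((nt, nt))
    Sj = np.block([[sc.Sigma_a, Sam], [Sam.T, sc.Sigma_m]])
    if np.linalg.eigvalsh(Sj).min() < -1e-10:
        raise ValueError("joint (a, m) covariance is not positive semi-definite")
    Lj = _safe_chol(Sj)
    am = np.empty((n, 2 * nt))
    z = rng.standard_normal((n, 2 * nt))

    # under truncation selection, the heritable merit simulated inside the
    # pedigree generator *is* the selected trait's autosomal value (scaled);
    # the remaining (a, m) components are drawn conditionally on it so the
    # joint covariance stays Sj
    sel_t = None
    if sc.selection is not None and "sel_merit" in ped.df.columns:
        sel_t = sc.traits.index(sc.selection[1])
        merit = ped.df["sel_merit"].to_numpy(float)
        sd_sel = np.sqrt(Sj[sel_t, sel_t])
        rest = [k for k in range(2 * nt) if k != sel_t]
        beta = Sj[rest, sel_t] / Sj[sel_t, sel_t]
        schur = Sj[np.ix_(rest, rest)] - np.outer(beta, Sj[sel_t, rest])
        Lr = _safe_chol(schur)

    for i in range(n):
        s, d = sire[i], dam[i]
        mean = np.zeros(2 * nt)
        w = 1.0
        if s >= 0 and d >= 0:
            mean = 0.5 * (am[s] + am[d])
            w = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            mean = 0.5 * am[s]
            w = 0.75 - 0.25 * F[s]
        elif d >= 0:
            mean = 0.5 * am[d]
            w = 0.75 - 0.25 * F[d]
        if sel_t is None:
            am[i] = mean + np.sqrt(w) * (Lj @ z[i])
        else:
            am[i, sel_t] = sd_sel * merit[i]
            phi_sel = am[i, sel_t] - mean[sel_t]
            am[i, rest] = mean[rest] + beta * phi_sel + np.sqrt(w) * (Lr @ z[i, : len(rest)])
    a = am[:, :nt]
    m = am[:, nt:]

    # X-linked: gamete-level descent
    Fx = xlinked_inbreeding(ped)
    Ls = _safe_chol(0.5 * sc.Sigma_s)
    gam_m = np.empty((n, nt))  # maternal gamete value of each animal
    gam_p = np.zeros((n, nt))  # paternal gamete value (females only)
    zm = rng.standard_normal((n, nt))
    for i in range(n):
        d = dam[i]
        if d < 0:
            gam_m[i] = Ls @ zm[i]
        else:
            if sex[d] == FEMALE:
                mid = 0.5 * (gam_p[d] + gam_m[d])
                w = 0.5 * (1.0 - Fx[d])
            else:  # dam recorded male would have been rejected upstream
                mid = gam_m[d]
                w = 0.0
            gam_m[i] = mid + np.sqrt(w) * (Ls @ zm[i])
        if sex[i] == FEMALE:
            s = sire[i]
            if s < 0:
                gam_p[i] = Ls @ rng.standard_normal(nt)
            else:
                gam_p[i] = gam_m[s]  # the sire's whole X, intact
    svals = gam_m + gam_p
    return {"a": a, "s": svals, "m": m}


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    ped: Pedigree,
    bvs: dict[str, np.ndarray],
    sc: SimulationScenario,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phenotype records for every non-founder kid.

    Output columns: animal_id, dam_id, sex, birth_date, birth_year,
    birth_month, birth_type, dam_age, parity, weaning_age and one column
    per base trait (WWT missing at random for a configurable fraction).
    """
    rng = np.random.default_rng((sc.seed + 2) if seed is None else seed)
    df = ped.df
    nt = len(sc.traits)
    kids = df[df["sire"].notna() & df["dam"].notna()].index.to_numpy()
    dam_pos = np.array([ped.position(d) for d in df.loc[kids, "dam"]])
    dam_ids = df.loc[kids, "dam"].to_numpy()

    # maternal permanent environment, one draw per dam, on pe_traits only
    pe_idx = [sc.traits.index(t) for t in sc.pe_traits]
    Lpe = _safe_chol(sc.Sigma_pe)
    pe_by_dam: dict[int, np.ndarray] = {}
    for dp in np.unique(dam_pos):
        v = np.zeros(nt)
        v[pe_idx] = Lpe @ rng.standard_normal(len(pe_idx))
        pe_by_dam[dp] = v

    Le = _safe_chol(sc.Sigma_e)
    e = (Le @ rng.standard_normal((nt, len(kids)))).T

    months = df.loc[kids, "birth_date"].dt.month.to_numpy()
    years = df.loc[kids, "birth_date"].dt.year.to_numpy()
    sexes = df.loc[kids, "sex"].to_numpy()
    btype = df.loc[kids, "birth_type"].to_numpy() if "birth_type" in df else np.ones(len(kids), int)
    dage = df.loc[kids, "dam_age"].to_numpy() if "dam_age" in df else np.full(len(kids), 2)
    parity = df.loc[kids, "parity"].to_numpy() if "parity" in df else np.ones(len(kids), int)

    y = np.empty((len(kids), nt))
    yspan = sc.birth_year_span
    for t, trait in enumerate(sc.traits):
        fe = np.full(len(kids), sc.mu[trait])
        fe += np.where(sexes == MALE, sc.sex_effect[trait], -sc.sex_effect[trait])
        fe += sc.year_effect_amplitude[trait] * np.sin(
            2.0 * np.pi * (years - sc.birth_year_start) / max(yspan - 1, 1)
        )
        fe += sc.month_effect_amplitude[trait] * np.cos(2.0 * np.pi * (months - 3) / 12.0)
        bt_eff = np.asarray(sc.birth_type_effect[trait])
        fe += bt_eff[np.clip(btype, 1, 3) - 1]
        fe += sc.dam_age_slope[trait] * (np.minimum(dage, 6) - 3)
        fe += sc.parity_slope[trait] * (np.minimum(parity, 4) - 2)
        y[:, t] = (
            fe
            + bvs["a"][kids, t]
            + bvs["s"][kids, t]
            + bvs["m"][dam_pos, t]
            + np.array([pe_by_dam[dp][t] for dp in dam_pos])
            + e[:, t]
        )

    wage = rng.normal(sc.weaning_age_mean, sc.weaning_age_sd, len(kids))
    wage = np.clip(wage, 40.0, 160.0).round(0)
    out = pd.DataFrame(
        {
            "animal_id": df.loc[kids, "animal"].to_numpy(),
            "sire_id": df.loc[kids, "sire"].to_numpy(),
            "dam_id": dam_ids,
            "sex": sexes,
            "birth_date": df.loc[kids, "birth_date"].to_numpy(),
            "birth_year": years,
            "birth_month": months,
            "birth_type": btype,
            "dam_age": dage,
            "parity": parity,
            "weaning_age": wage,
        }
    )
    for t, trait in enumerate(sc.traits):
        out[trait] = y[:, t]
    if "WWT" in sc.traits and sc.wwt_missing_fraction > 0:
        miss = rng.random(len(out)) < sc.wwt_missing_fraction
        out.loc[miss, "WWT"] = np.nan
        out.loc[miss, "weaning_age"] = np.nan
    return out


def true_components(sc: SimulationScenario, spec) -> "VarianceComponents":
    """The scenario's generating (co)variances arranged as a model's blocks.

    Useful as a fitting oracle (parameter-recovery studies) and for BLUP at
    known components.  Blocks of the model that the scenario does not
    generate (e.g. a free direct-maternal covariance when sigma_am is zero)
    are filled with zeros.
    """
    from .models import VarianceComponents

    src = {"AAG": sc.Sigma_a, "SLAG": sc.Sigma_s, "MGE": sc.Sigma_m, "R": sc.Sigma_e}
    ti = {t: k for k, t in enumerate(sc.traits)}
    pe_ti = {t: k for k, t in enumerate(sc.pe_traits)}
    Sam = sc.sigma_am if sc.sigma_am is not None else np.zeros((len(sc.traits),) * 2)
    blocks = {}
    for name, pairs, structure in spec.blocks():
        k = len(pairs)
        B = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                (term_a, tr_a), (term_b, tr_b) = pairs[a], pairs[b]
                if term_a == term_b == "MPE":
                    B[a, b] = sc.Sigma_pe[pe_ti[tr_a], pe_ti[tr_b]]
                elif term_a == term_b:
                    B[a, b] = src[term_a][ti[tr_a], ti[tr_b]]
                elif {term_a, term_b} == {"AAG", "MGE"}:
                    i, j = (ti[tr_a], ti[tr_b]) if term_a == "AAG" else (ti[tr_b], ti[tr_a])
                    B[a, b] = Sam[i, j]
        blocks[name] = B
    vc = VarianceComponents(spec, blocks, n_free_parameters=spec.n_parameters())
    return vc


def simulate_dataset(
    sc: SimulationScenario | None = None, seed: int | None = None
) -> tuple[Pedigree, pd.DataFrame, dict[str, np.ndarray]]:
    """Convenience end-to-end draw: pedigree, phenotypes, true breeding values."""
    sc = sc or default_scenario()
    base = sc.seed if seed is None else seed
    ped = simulate_pedigree(sc, seed=base)
    bvs = simulate_breeding_values(ped, sc, seed=base + 1)
    phen = simulate_phenotypes(ped, bvs, sc, seed=base + 2)
    return ped, phen, bvs
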