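"""REML engine: likelihood correctness, estimation, selection, derived parameters."""

import numpy as np
import pandas as pd
import pytest

from hircus.design import build_design, pedigree_structures
from hircus.kinship import build_A, build_S
from hircus.models import ModelSpec, VarianceComponents, model_preset
from hircus.reml import (
    LOG2PI,
    MixedModel,
    fit_reml,
    genetic_correlations,
    genetic_parameters,
    select_model,
)
from hircus.simulate import true_components

FIVE = ("BWT", "WWT", "PWGR", "PWKR", "PWGE")


def dense_reml_loglik(dm, mm, vc, ped):
    """Independent oracle: REML likelihood through the dense covariance V."""
    A = build_A(ped).values
    S = build_S(ped).values
    Kd = {"A": A, "S": S}
    n_obs = dm.n_obs
    V = np.zeros((n_obs, n_obs))
    for name, pairs, structure in vc.spec.blocks():
        if structure == "R":
            continue
        K = Kd.get(structure, np.eye(dm.n_levels[name]))
        Z = dm.Z[name].toarray()
        V += Z @ np.kron(vc.blocks[name], K) @ Z.T
    for pk, pattern in enumerate(dm.patterns):
        recs = mm._pattern_records[pk]
        starts = mm._rec_start[recs]
        obs = list(pattern)
        Sub = vc.blocks["R"][np.ix_(obs, obs)]
        for s0 in starts:
            V[s0 : s0 + len(obs), s0 : s0 + len(obs)] += Sub
    X = dm.X.toarray()
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + dm.y @ P @ dm.y
        + (n_obs - X.shape[1]) * LOG2PI
    )


@pytest.mark.parametrize("preset", ["model1", "model2", "model3", "model4"])
def test_mme_loglik_equals_dense_V_oracle(tiny_herd, preset):
    sc, ped, phen, _ = tiny_herd
    spec = model_preset(preset, sc.traits, {t: ["sex"] for t in sc.traits})
    st = pedigree_structures(ped)
    dm = build_design(phen, ped, spec, st)
    mm = MixedModel(dm, st)
    vc = true_components(sc, spec)
    # make every block strictly PD (the scenario's cross block is zero)
    for nm in vc.blocks:
        k = vc.blocks[nm].shape[0]
        vc.blocks[nm] = vc.blocks[nm] + 1e-4 * np.eye(k)
    logL = mm.loglik(vc)
    assert logL == pytest.approx(dense_reml_loglik(dm, mm, vc, ped), abs=1e-6)


def test_residual_only_model_matches_closed_form():
    rng = np.random.default_rng(0)
    n = 300
    y = 3.0 + rng.normal(0, 0.7, n)
    rec = pd.DataFrame(
        dict(animal_id=[f"x{i}" for i in range(n)], BWT=y)
    )
    ped_df = pd.DataFrame(
        dict(animal=[f"x{i}" for i in range(n)], sire=None, dam=None, sex="F",
             birth_date=pd.NaT)
    )
    from hircus.pedigree import Pedigree, sort_topological

    ped = sort_topological(Pedigree(ped_df))
    spec = ModelSpec(("BWT",), {"BWT": []}, {})
    vc = fit_reml(spec, rec, ped, structures=pedigree_structures(ped, with_S=False))
    s2_hat = float(vc.blocks["R"][0, 0])
    rss = np.sum((y - y.mean()) ** 2)
    assert s2_hat == pytest.approx(rss / (n - 1), rel=1e-6)
    expected_logL = -0.5 * (
        (n - 1) * np.log(s2_hat) + np.log(n) + rss / s2_hat + (n - 1) * LOG2PI
    )
    assert vc.logL == pytest.approx(expected_logL, abs=1e-6)
    assert vc.AIC == -2 * vc.logL + 2 * vc.n_free_parameters


def test_loglik_scaling_identity(tiny_herd):
    sc, ped, phen, _ = tiny_herd
    spec = model_preset("model1", sc.traits, {t: ["sex"] for t in sc.traits})
    st = pedigree_structures(ped)
    c = 3.0
    vc = true_components(sc, spec)
    dm = build_design(phen, ped, spec, st)
    mm = MixedModel(dm, st)
    logL1 = mm.loglik(vc)
    phen2 = phen.copy()
    for t in sc.traits:
        phen2[t] = phen2[t] * c
    vc2 = vc.with_free_vector(vc.free_vector() * c**2)
    dm2 = build_design(phen2, ped, spec, st)
    mm2 = MixedModel(dm2, st)
    logL2 = mm2.loglik(vc2)
    n_contrast = dm.n_obs - dm.X.shape[1]
    assert logL2 == pytest.approx(logL1 - n_contrast * np.log(c), abs=1e-6)


def test_record_order_invariance(small_herd):
    sc, ped, phen, _ = small_herd
    spec = model_preset("model2", sc.traits, {t: ["sex"] for t in sc.traits})
    st = pedigree_structures(ped)
    fit1 = fit_reml(spec, phen, ped, structures=st, max_iter=25)
    shuffled = phen.sample(frac=1.0, random_state=1).reset_index(drop=True)
    fit2 = fit_reml(spec, shuffled, ped, structures=st, max_iter=25)
    # agreement is limited by the optimizer's stopping point on a flat
    # likelihood ridge, not by the algebra (logL agrees to ~1e-12)
    assert fit2.logL == pytest.approx(fit1.logL, abs=1e-6)
    np.testing.assert_allclose(fit1.free_vector(), fit2.free_vector(), atol=1e-6)


class TestSelectModel:
    def test_requires_two_candidates(self, small_herd):
        sc, ped, phen, _ = small_herd
        spec = model_preset("model3", sc.traits, {t: [] for t in sc.traits})
        with pytest.raises(ValueError):
            select_model([spec], phen, ped)

    def test_identical_candidates_tie_break_by_order(self, small_herd):
        sc, ped, phen, _ = small_herd
        st = pedigree_structures(ped)
        a = model_preset("model3", sc.traits, {t: ["sex"] for t in sc.traits})
        b = model_preset("model3", sc.traits, {t: ["sex"] for t in sc.traits})
        a.name, b.name = "first", "second"
        out = select_model([a, b], phen, ped, structures=st, max_iter=15)
        assert out["model"].iloc[0] == "first"
        assert out["dAIC"].iloc[0] == 0.0
        assert (out["dAIC"] >= 0).all()


@pytest.fixture(scope="module")
def fitted_like_components():
    """Five-trait component table with magnitudes typical for goat
    early-growth analyses (kg^2 for weights, larger scales for rates)."""
    spec = model_preset("model1", FIVE, {t: [] for t in FIVE}, pe_traits=("BWT",))
    vals = {
        "AAG": [0.007, 0.126, 22.96, 0.676, 440.41],
        "SLAG": [0.004, 0.036, 5.18, 0.062, 291.24],
        "MGE": [0.018, 0.061, 20.15, 0.370, 589.06],
        "R": [0.108, 1.430, 320.80, 6.70, 5885.20],
    }
    blocks = {}
    for nm, pairs, _ in spec.blocks():
        k = len(pairs)
        B = np.zeros((k, k))
        if nm == "MPE":
            B[0, 0] = 0.001
        else:
            np.fill_diagonal(B, vals[nm][: k])
        blocks[nm] = B
    vc = VarianceComponents(spec, blocks, n_free_parameters=spec.n_parameters())
    return genetic_parameters(vc)


class TestGeneticParameters:
    def test_birth_weight_ratios(self, fitted_like_components):
        row = fitted_like_components.table.loc["BWT"]
        assert row["sigma_P"] == pytest.approx(0.138)
        assert round(row["h2_a"], 2) == 0.05
        assert round(row["h2_s"], 2) == 0.03
        assert round(row["h2_m"], 2) == 0.13
        assert round(row["pe2"], 2) == 0.01

    def test_sexlinked_share_range(self, fitted_like_components):
        share = fitted_like_components.sexlinked_share
        assert share.idxmax() == "PWGE"
        assert round(share["PWGE"]) == 40
        assert round(share["PWKR"]) == 8

    def test_residual_only_gives_zero_ratios(self):
        spec = ModelSpec(("BWT",), {}, {"AAG": ("BWT",)})
        vc = VarianceComponents(
            spec, {"AAG": np.array([[0.0]]), "R": np.array([[1.0]])},
            n_free_parameters=2,
        )
        t = genetic_parameters(vc).table
        assert t.loc["BWT", "h2_a"] == 0.0


class TestGeneticCorrelations:
    def test_diagonal_is_one(self):
        S = np.array([[2.0, 0.6], [0.6, 1.5]])
        R = genetic_correlations(S)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_perfect_correlation(self):
        S = np.array([[4.0, 6.0], [6.0, 9.0]])
        R = genetic_correlations(S)
        assert R[0, 1] == pytest.approx(1.0)

    def test_negative_diagonal_raises(self):
        with pytest.raises(ValueError):
            genetic_correlations(np.array([[-1.0, 0.0], [0.0, 1.0]]))

    def test_zero_variance_flagged_nan(self):
        R = genetic_correlations(np.array([[0.0, 0.0], [0.0, 2.0]]))
        assert np.isnan(R[0, 1]) and np.isnan(R[0, 0])
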