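"""Synthetic-herd generator: structure, conventions, determinism."""

import numpy as np
import pandas as pd
import pytest

from hircus.kinship import build_S
from hircus.pedigree import validate_and_repair
from hircus.simulate import (
    SimulationScenario,
    default_scenario,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
    simulate_phenotypes,
    true_components,
)


class TestScenario:
    def test_default_scenario_validates_and_is_frozen(self):
        a, b = default_scenario(), default_scenario()
        assert a.describe() == b.describe()
        assert a.does_per_buck == 15
        assert a.birth_year_span == 8
        assert a.weaning_age_mean == 80.0
        np.testing.assert_allclose(np.diag(a.Sigma_a), [0.007, 0.126])
        np.testing.assert_allclose(np.diag(a.Sigma_s), [0.004, 0.036])
        np.testing.assert_allclose(np.diag(a.Sigma_m), [0.018, 0.061])
        np.testing.assert_allclose(np.diag(a.Sigma_e), [0.108, 1.430])
        assert a.Sigma_pe[0, 0] == 0.001

    def test_bad_litter_probs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationScenario(litter_probs={1: 0.5, 2: 0.4})

    def test_non_psd_block_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationScenario(Sigma_a=np.array([[1.0, 2.0], [2.0, 1.0]]))


@pytest.fixture(scope="module")
def herd():
    sc = SimulationScenario(
        n_generations=2, n_dams_per_generation=60, does_per_buck=15, seed=1
    )
    return sc, simulate_pedigree(sc, seed=1)


class TestPedigree:
    def test_mating_ratio_realised(self, herd):
        sc, ped = herd
        kids = ped.df[ped.df["sire"].notna()]
        per_sire = kids.groupby("sire")["dam"].nunique()
        assert per_sire.mean() == pytest.approx(15, abs=3)

    def test_seeded_determinism(self, herd):
        sc, ped = herd
        again = simulate_pedigree(sc, seed=1)
        pd.testing.assert_frame_equal(ped.df, again.df)

    def test_passes_validation_cleanly(self, herd):
        _, ped = herd
        fixed, report = validate_and_repair(ped)
        assert len(report) == 0

    def test_parents_precede_offspring(self, herd):
        _, ped = herd
        sire, dam = ped.parent_indices()
        idx = np.arange(len(ped))
        assert ((sire < idx) | (sire == -1)).all()
        assert ((dam < idx) | (dam == -1)).all()

    def test_infeasible_plan_rejected(self):
        sc = SimulationScenario(n_generations=2, n_dams_per_generation=5,
                                does_per_buck=1, seed=0)
        # 5 sires needed for 5 dams, fine; but more sires than dams fails
        sc2 = SimulationScenario(n_generations=1, n_dams_per_generation=3,
                                 does_per_buck=1, seed=0)
        simulate_pedigree(sc2, seed=0)  # boundary case runs


class TestBreedingValues:
    def test_base_population_covariances_match_convention(self):
        # many founders, no structure: empirical covariances hit the blocks
        sc = SimulationScenario(
            n_generations=1, n_dams_per_generation=4000, does_per_buck=15, seed=3
        )
        ped = simulate_pedigree(sc, seed=3)
        bvs = simulate_breeding_values(ped, sc, seed=4)
        df = ped.df
        founders = (df["sire"].isna() & (df["sex"] == "F")).to_numpy()
        s_f = bvs["s"][founders]
        emp = np.cov(s_f.T)
        # base females: Cov(s) = Sigma_s
        np.testing.assert_allclose(emp, sc.Sigma_s, atol=4 * 0.036 / np.sqrt(founders.sum()))
        a_f = bvs["a"][founders]
        np.testing.assert_allclose(np.cov(a_f.T), sc.Sigma_a,
                                   atol=4 * 0.126 / np.sqrt(founders.sum()))

    def test_males_carry_half_the_x_variance(self):
        sc = SimulationScenario(
            n_generations=2, n_dams_per_generation=900, does_per_buck=15, seed=5
        )
        ped = simulate_pedigree(sc, seed=5)
        bvs = simulate_breeding_values(ped, sc, seed=6)
        sex = ped.sex_codes
        vm = bvs["s"][sex == "M", 1].var()
        vf = bvs["s"][sex == "F", 1].var()
        assert vm / vf == pytest.approx(0.5, abs=0.12)

    def test_sire_son_x_independence(self):
        sc = SimulationScenario(
            n_generations=2, n_dams_per_generation=900, does_per_buck=10, seed=7
        )
        ped = simulate_pedigree(sc, seed=7)
        bvs = simulate_breeding_values(ped, sc, seed=8)
        df = ped.df
        sons = df[(df["sex"] == "M") & df["sire"].notna()]
        pos = {a: i for i, a in enumerate(df["animal"])}
        s_son = bvs["s"][[pos[a] for a in sons["animal"]], 1]
        s_sire = bvs["s"][[pos[a] for a in sons["sire"]], 1]
        r = np.corrcoef(s_son, s_sire)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(sons))

    def test_midparent_regression_is_unity(self):
        sc = SimulationScenario(
            n_generations=3, n_dams_per_generation=700, does_per_buck=10, seed=9
        )
        ped = simulate_pedigree(sc, seed=9)
        bvs = simulate_breeding_values(ped, sc, seed=10)
        sire, dam = ped.parent_indices()
        kids = np.where((sire >= 0) & (dam >= 0))[0]
        mid = 0.5 * (bvs["a"][sire[kids], 1] + bvs["a"][dam[kids], 1])
        kid = bvs["a"][kids, 1]
        slope = np.cov(kid, mid)[0, 1] / mid.var()
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_gene_drop_consistency_of_x_values(self):
        # empirical Cov(s) across many independent redraws on one pedigree
        # equals sigma_s^2 * S, the same structure the estimator assumes
        sc = SimulationScenario(
            n_generations=2, n_dams_per_generation=12, does_per_buck=4, seed=11,
            Sigma_a=np.diag([0.007, 0.126]), Sigma_s=np.diag([0.02, 0.1]),
        )
        ped = simulate_pedigree(sc, seed=11)
        S = build_S(ped).values
        draws = np.array(
            [simulate_breeding_values(ped, sc, seed=1000 + r)["s"][:, 0]
             for r in range(4000)]
        )
        emp = draws.T @ draws / len(draws)
        target = 0.02 * S
        assert np.abs(emp - target).max() < 5 * 0.02 / np.sqrt(4000) * 4


class TestPhenotypes:
    def test_zero_variance_gives_pure_fixed_effects(self):
        z = np.zeros((2, 2))
        sc = SimulationScenario(
            n_generations=2, n_dams_per_generation=30, does_per_buck=5, seed=13,
            Sigma_a=z, Sigma_s=z, Sigma_m=z, Sigma_pe=np.zeros((1, 1)), Sigma_e=z,
            sex_effect={"BWT": 0.0, "WWT": 0.0},
            year_effect_amplitude={"BWT": 0.0, "WWT": 0.0},
            month_effect_amplitude={"BWT": 0.0, "WWT": 0.0},
            birth_type_effect={"BWT": (0, 0, 0), "WWT": (0, 0, 0)},
            dam_age_slope={"BWT": 0.0, "WWT": 0.0},
            parity_slope={"BWT": 0.0, "WWT": 0.0},
            wwt_missing_fraction=0.0,
        )
        ped, phen, _ = simulate_dataset(sc, seed=13)
        np.testing.assert_allclose(phen["BWT"], sc.mu["BWT"], atol=1e-12)
        np.testing.assert_allclose(phen["WWT"], sc.mu["WWT"], atol=1e-12)

    def test_default_means_on_target(self):
        ped, phen, _ = simulate_dataset(default_scenario(), seed=21)
        se = phen["BWT"].std() / np.sqrt(len(phen))
        assert abs(phen["BWT"].mean() - 2.58) < 4 * se + 0.02
        assert abs(phen["WWT"].mean() - 10.58) < 0.2

    def test_end_to_end_determinism(self):
        sc = SimulationScenario(n_generations=2, n_dams_per_generation=40,
                                does_per_buck=8, seed=17)
        _, p1, _ = simulate_dataset(sc, seed=17)
        _, p2, _ = simulate_dataset(sc, seed=17)
        pd.testing.assert_frame_equal(p1, p2)

    def test_wwt_missingness_fraction(self):
        ped, phen, _ = simulate_dataset(default_scenario(), seed=23)
        frac = phen["WWT"].isna().mean()
        assert frac == pytest.approx(0.53, abs=0.03)


def test_true_components_layout():
    sc = default_scenario()
    from hircus.models import model_preset

    spec = model_preset("model1", sc.traits, {t: [] for t in sc.traits})
    vc = true_components(sc, spec)
    assert vc.get("AAG", "BWT") == pytest.approx(0.007)
    assert vc.get("SLAG", "WWT") == pytest.approx(0.036)
    assert vc.get("MPE", "BWT") == pytest.approx(0.001)
    assert vc.get("R", "BWT", "WWT") == pytest.approx(sc.Sigma_e[0, 1])
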