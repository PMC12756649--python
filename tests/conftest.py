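import numpy as np
import pandas as pd
import pytest

from hircus.pedigree import Pedigree, sort_topological, validate_and_repair
from hircus.simulate import (
    SimulationScenario,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)


def make_pedigree(rows):
    """rows: (animal, sire, dam, sex) tuples; returns validated+sorted Pedigree."""
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex"])
    df["birth_date"] = pd.NaT
    ped, _ = validate_and_repair(Pedigree(df))
    return sort_topological(ped)


def random_pedigree(n_founders, n_offspring, seed, p_male=0.5, n_active_sires=None):
    """Random-mating pedigree; every offspring has two known parents."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for j in range(n_founders):
        sx = "M" if j < max(2, n_founders // 4) else "F"
        rows.append((f"f{j}", None, None, sx))
        (males if sx == "M" else females).append(f"f{j}")
    sires = males[: n_active_sires or len(males)]
    for j in range(n_offspring):
        s = rng.choice(sires)
        d = rng.choice(females)
        sx = "M" if rng.random() < p_male else "F"
        rows.append((f"a{j}", s, d, sx))
        (males if sx == "M" else females).append(f"a{j}")
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def trio_ped():
    return make_pedigree(
        [("s1", None, None, "M"), ("d1", None, None, "F"), ("k1", "s1", "d1", "F")]
    )


@pytest.fixture(scope="session")
def small_herd():
    """~250-record herd, enough signal for design/BLUP plumbing tests."""
    sc = SimulationScenario(
        n_generations=3, n_dams_per_generation=55, does_per_buck=5, seed=42
    )
    ped = simulate_pedigree(sc, seed=42)
    bvs = simulate_breeding_values(ped, sc, seed=43)
    phen = simulate_phenotypes(ped, bvs, sc, seed=44)
    return sc, ped, phen, bvs


@pytest.fixture(scope="session")
def tiny_herd():
    """<40 animals; dense oracles stay cheap."""
    sc = SimulationScenario(
        n_generations=2, n_dams_per_generation=8, does_per_buck=4, seed=7
    )
    ped = simulate_pedigree(sc, seed=7)
    bvs = simulate_breeding_values(ped, sc, seed=8)
    phen = simulate_phenotypes(ped, bvs, sc, seed=9)
    return sc, ped, phen, bvs
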