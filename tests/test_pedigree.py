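"""Pedigree I/O, repair, ordering, inbreeding and summary statistics."""

import io

import numpy as np
import pandas as pd
import pytest

from hircus.pedigree import (
    Pedigree,
    PedigreeError,
    generation_numbers,
    inbreeding,
    pedigree_depths,
    pedigree_statistics,
    read_pedigree,
    sort_topological,
    validate_and_repair,
)

from conftest import make_pedigree, random_pedigree


def _csv(text):
    return io.StringIO(text.strip())


class TestReadPedigree:
    def test_three_line_file_resolves_links(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\ns1,,,M\nd1,,,F\nk1,s1,d1,F")
        )
        assert len(ped) == 3
        assert ped.df.loc[2, "sire"] == "s1"
        assert ped.df.loc[2, "dam"] == "d1"

    def test_unknown_parent_tokens_normalised(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\na,0,NA,M\nb,,-,F")
        )
        assert ped.df["sire"].isna().all() or ped.df["sire"].isnull().all()

    def test_offspring_before_parents_accepted(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\nk1,s1,d1,F\ns1,,,M\nd1,,,F")
        )
        assert len(ped) == 3  # ordering deferred to sort

    def test_conflicting_duplicate_is_error(self):
        with pytest.raises(PedigreeError, match="conflicting parents"):
            read_pedigree(
                _csv("animal,sire,dam,sex\ns1,,,M\ns2,,,M\nd,,,F\n"
                     "k,s1,d,F\nk,s2,d,F")
            )

    def test_missing_column_is_error(self):
        with pytest.raises(PedigreeError, match="missing mandatory column"):
            read_pedigree(_csv("animal,sire,sex\na,,M"))


class TestValidateRepair:
    def test_own_parent_link_severed(self):
        ped = read_pedigree(_csv("animal,sire,dam,sex\na,a,,M"))
        fixed, report = validate_and_repair(ped)
        assert fixed.df.loc[fixed.df.animal == "a", "sire"].isna().all()
        assert any(i["issue_code"] == "own-parent" for i in report.issues)

    def test_exact_duplicate_collapsed(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\ns,,,M\nd,,,F\nk,s,d,F\nk,s,d,F")
        )
        fixed, report = validate_and_repair(ped)
        assert len(fixed) == 4 - 1
        assert any(i["issue_code"] == "duplicate_record" for i in report.issues)

    def test_two_cycle_is_hard_error(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\nA,B,,M\nB,A,,M")
        )
        with pytest.raises(PedigreeError, match="cycle"):
            validate_and_repair(ped)
        # error names the members
        try:
            validate_and_repair(ped)
        except PedigreeError as e:
            assert "A" in str(e) and "B" in str(e)

    def test_clean_pedigree_untouched_and_idempotent(self, trio_ped):
        fixed, report = validate_and_repair(trio_ped)
        assert len(report) == 0
        again, report2 = validate_and_repair(fixed)
        assert len(report2) == 0
        pd.testing.assert_frame_equal(
            fixed.df.reset_index(drop=True), again.df.reset_index(drop=True)
        )

    def test_sex_conflict_corrected_by_role(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\np1,,,F\nd1,,,F\nk1,p1,d1,M")
        )
        fixed, report = validate_and_repair(ped)
        assert fixed.df.loc[fixed.df.animal == "p1", "sex"].iloc[0] == "M"
        assert any(i["issue_code"] == "sex_conflict" for i in report.issues)


class TestSort:
    def test_reversed_order_sorted(self):
        ped = read_pedigree(
            _csv("animal,sire,dam,sex\nk1,s1,d1,F\ns1,,,M\nd1,,,F")
        )
        fixed, _ = validate_and_repair(ped)
        srt = sort_topological(fixed)
        pos = {a: i for i, a in enumerate(srt.animals)}
        assert pos["s1"] < pos["k1"] and pos["d1"] < pos["k1"]

    def test_idempotent(self, trio_ped):
        again = sort_topological(trio_ped)
        assert list(again.animals) == list(trio_ped.animals)

    def test_random_permutation_of_simulated_pedigree(self):
        ped = random_pedigree(12, 50, seed=3)
        rng = np.random.default_rng(0)
        shuffled = Pedigree(
            ped.df.iloc[rng.permutation(len(ped))].reset_index(drop=True)
        )
        shuffled.validated = True
        srt = sort_topological(shuffled)
        sire, dam = srt.parent_indices()
        for i in range(len(srt)):  # brute-force scan: parents precede children
            assert sire[i] < i or sire[i] == -1
            assert dam[i] < i or dam[i] == -1


def kinship_recursive(ped):
    """Independent oracle: classic recursive kinship (coefficient de parenté)."""
    sire, dam = ped.parent_indices()
    from functools import lru_cache

    import sys
    sys.setrecursionlimit(100000)

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        if i == j:
            return 0.5 * (1.0 + phi(sire[i], dam[i]))
        return 0.5 * (phi(sire[i], j) + phi(dam[i], j))

    return phi


class TestInbreeding:
    def test_fullsib_offspring(self):
        ped = make_pedigree(
            [("s", None, None, "M"), ("d", None, None, "F"),
             ("b", "s", "d", "M"), ("g", "s", "d", "F"), ("k", "b", "g", "F")]
        )
        F = inbreeding(ped)
        assert F[ped.position("k")] == pytest.approx(0.25)

    def test_halfsib_offspring(self):
        ped = make_pedigree(
            [("s", None, None, "M"), ("d1", None, None, "F"), ("d2", None, None, "F"),
             ("b", "s", "d1", "M"), ("g", "s", "d2", "F"), ("k", "b", "g", "F")]
        )
        F = inbreeding(ped)
        assert F[ped.position("k")] == pytest.approx(0.125)

    def test_matches_recursive_kinship_oracle(self):
        ped = random_pedigree(14, 200, seed=11, n_active_sires=4)
        F = inbreeding(ped)
        phi = kinship_recursive(ped)
        sire, dam = ped.parent_indices()
        F_oracle = np.array(
            [phi(sire[i], dam[i]) if sire[i] >= 0 and dam[i] >= 0 else 0.0
             for i in range(len(ped))]
        )
        np.testing.assert_allclose(F, F_oracle, atol=1e-12)
        assert F.max() > 0  # the pedigree actually contains inbreeding

    def test_requires_sorted(self):
        df = pd.DataFrame(
            [("k", "s", "d", "F"), ("s", None, None, "M"), ("d", None, None, "F")],
            columns=["animal", "sire", "dam", "sex"],
        )
        df["birth_date"] = pd.NaT
        with pytest.raises(PedigreeError, match="sorted"):
            inbreeding(Pedigree(df))


class TestStatistics:
    def test_fullsib_family_and_completeness(self):
        ped = make_pedigree(
            [("s", None, None, "M"), ("d", None, None, "F"),
             ("k1", "s", "d", "F"), ("k2", "s", "d", "M"), ("k3", "s", "d", "F")]
        )
        st = pedigree_statistics(ped)
        assert st.fullsib_family_count == 1
        assert st.mean_fullsib_family_size == 3
        assert st.completeness_fraction == pytest.approx(3 / 5)
        assert st.n_generations == 2

    def test_all_founders(self):
        ped = make_pedigree([(f"f{i}", None, None, "F") for i in range(6)])
        st = pedigree_statistics(ped)
        assert st.completeness_fraction == 0
        assert st.n_generations == 1
        assert st.n_inbred == 0

    def test_against_edge_list_recomputation(self):
        ped = random_pedigree(10, 80, seed=5)
        st = pedigree_statistics(ped)
        df = ped.df
        # independent traversal on the raw edge list
        parents = {r.animal: (r.sire, r.dam) for r in df.itertuples()}

        def gen(a):
            s, d = parents[a]
            gs = gen(s) + 1 if isinstance(s, str) else 0
            gd = gen(d) + 1 if isinstance(d, str) else 0
            return max(gs, gd)

        gens = [gen(a) for a in df.animal]
        assert st.n_generations == max(gens) + 1
        both = df.sire.notna() & df.dam.notna()
        assert st.completeness_fraction == pytest.approx(both.mean())
        fams = df.loc[both].groupby(["sire", "dam"]).size()
        assert st.fullsib_family_count == (fams >= 2).sum()

    def test_depth_of_two_generation_animal(self):
        ped = make_pedigree(
            [("s", None, None, "M"), ("d", None, None, "F"), ("k", "s", "d", "F")]
        )
        depth = pedigree_depths(ped)
        assert depth[ped.position("k")] == pytest.approx(1.0)  # both parents known
        gens = generation_numbers(ped)
        assert gens[ped.position("k")] == 1
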