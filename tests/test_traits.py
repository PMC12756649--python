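"""Trait derivation, outlier QC, summaries and fixed-effect screening."""

import numpy as np
import pandas as pd
import pytest

from hircus.traits import (
    data_structure_table,
    derive_traits,
    filter_outliers,
    screen_fixed_effects,
    summarize_trait,
)


def rec_frame(**cols):
    n = len(next(iter(cols.values())))
    base = dict(animal_id=[f"a{i}" for i in range(n)])
    base.update(cols)
    return pd.DataFrame(base)


class TestDeriveTraits:
    def test_growth_rate_from_typical_weights(self):
        # 2.58 kg at birth, 10.58 kg at an 80-day weaning -> 100 g/day
        rec, _ = derive_traits(
            rec_frame(BWT=[2.58], WWT=[10.58], weaning_age=[80.0])
        )
        assert rec["PWGR"].iloc[0] == pytest.approx(100.0)
        assert rec["PWKR"].iloc[0] == pytest.approx(100.0 / 10.58**0.75)
        assert rec["PWKR"].iloc[0] == pytest.approx(17.0465, abs=1e-3)

    def test_doubling_birth_to_weaning_gives_100_percent_efficiency(self):
        rec, _ = derive_traits(
            rec_frame(BWT=[1.7, 3.1], WWT=[3.4, 6.2], weaning_age=[70.0, 95.0])
        )
        np.testing.assert_allclose(rec["PWGE"], [100.0, 100.0])

    def test_efficiency_scale_invariant(self):
        a, _ = derive_traits(rec_frame(BWT=[2.0], WWT=[9.0], weaning_age=[80.0]))
        b, _ = derive_traits(rec_frame(BWT=[4.0], WWT=[18.0], weaning_age=[80.0]))
        assert a["PWGE"].iloc[0] == pytest.approx(b["PWGE"].iloc[0])

    def test_missing_weaning_data_skipped_with_log(self):
        rec, skipped = derive_traits(
            rec_frame(BWT=[2.5, 2.6], WWT=[10.0, np.nan], weaning_age=[80.0, np.nan])
        )
        assert rec["PWGR"].notna().tolist() == [True, False]
        assert len(skipped) == 1

    def test_nonpositive_birth_weight_rejected(self):
        with pytest.raises(ValueError, match="birth weight"):
            derive_traits(rec_frame(BWT=[0.0], WWT=[5.0], weaning_age=[80.0]))


class TestOutlierFilter:
    def test_constant_vector_untouched(self):
        kept, removed = filter_outliers(pd.Series([5.0] * 10))
        assert removed.empty
        assert kept.notna().all()

    def test_single_gross_outlier_removed(self):
        v = pd.Series([10.0] * 100 + [1000.0])
        # mean ~ 19.8, SD ~ 98.5: only the 1000 lies outside mean + 3 SD
        kept, removed = filter_outliers(v, 3)
        assert removed["value"].tolist() == [1000.0]
        assert kept.notna().sum() == 100

    def test_boundary_value_kept(self):
        base = pd.Series([-1.0, 1.0] * 50)
        m, s = base.mean(), base.std(ddof=1)
        v = pd.concat([base, pd.Series([m + 3 * s])], ignore_index=True)
        kept, removed = filter_outliers(v, 3)
        assert removed.empty  # closed interval

    def test_removals_nonincreasing_in_k(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.standard_normal(500))
        counts = [len(filter_outliers(v, k)[1]) for k in (1, 2, 3, 4)]
        assert counts == sorted(counts, reverse=True)

    def test_no_removal_when_all_within(self):
        v = pd.Series(np.linspace(-1, 1, 50))
        kept, removed = filter_outliers(v, 3)
        assert removed.empty


class TestSummaries:
    def test_cv_from_typical_birth_weights(self):
        # mean 2.58 kg, SD 0.38 kg -> CV 14.73 %
        d = 0.38 / np.sqrt(2)
        s = summarize_trait(pd.Series([2.58 - d, 2.58 + d]))
        assert s.mean == pytest.approx(2.58)
        assert s.SD == pytest.approx(0.38)
        assert round(s.CV_percent, 2) == 14.73

    def test_constant_vector(self):
        s = summarize_trait(pd.Series([3.0, 3.0, 3.0]))
        assert s.SD == 0 and s.CV_percent == 0

    def test_normal_sample_moments(self):
        rng = np.random.default_rng(123)
        s = summarize_trait(pd.Series(rng.standard_normal(200_000)))
        assert abs(s.skewness) < 0.02
        assert s.kurtosis == pytest.approx(3.0, abs=0.05)

    def test_cv_identity_property(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            v = pd.Series(rng.gamma(5, 2, 100))
            s = summarize_trait(v)
            assert s.CV_percent == pytest.approx(s.SD / s.mean * 100)

    def test_records_per_parent(self):
        n = 120
        df = rec_frame(
            BWT=np.full(n, 2.5) + np.linspace(0, 0.1, n),
            sire_id=[f"s{i % 8}" for i in range(n)],
            dam_id=[f"d{i % 40}" for i in range(n)],
        )
        t = data_structure_table(df, ["BWT"])
        assert t.loc["records_per_sire", "BWT"] == pytest.approx(120 / 8)
        assert t.loc["records_per_dam", "BWT"] == pytest.approx(120 / 40)


class TestScreening:
    def test_null_factor_not_significant_and_statistic_zero(self):
        # identical group means by construction: between-group sum of squares
        # is exactly zero, so F = 0 and p is as large as it gets
        n = 40
        df = rec_frame(
            y=np.tile([1.0, 2.0], n // 2),
            g=np.repeat(["a", "b"], n // 2),
        )
        res = screen_fixed_effects(df, ["g"], "y")
        assert res["anova"].loc["g", "F"] == pytest.approx(0.0, abs=1e-10)
        assert res["anova"].loc["g", "PR(>F)"] > 0.99
        assert "g" not in res["significant"]

    def test_balanced_ls_means_equal_raw_means(self):
        rng = np.random.default_rng(2)
        n = 200
        g = np.tile(["a", "b"], n // 2)
        h = np.repeat(["u", "v"], n // 2)
        y = 1.0 + (g == "b") * 0.5 + (h == "v") * 0.2 + rng.normal(0, 0.1, n)
        df = rec_frame(y=y, g=g, h=h)
        res = screen_fixed_effects(df, ["g", "h"], "y")
        ls = res["ls_means"].set_index(["factor", "level"])["ls_mean"]
        raw = pd.Series(y).groupby(g).mean()
        assert ls.loc[("g", "a")] == pytest.approx(raw["a"], abs=1e-8)
        assert ls.loc[("g", "b")] == pytest.approx(raw["b"], abs=1e-8)

    def test_sex_effect_detected_and_sized(self):
        rng = np.random.default_rng(7)
        n = 2000
        sex = rng.choice(["M", "F"], n)
        year = rng.choice([2016, 2017, 2018], n)
        y = 2.44 + (sex == "M") * 0.22 + rng.normal(0, 0.35, n)
        df = rec_frame(y=y, sex=sex, year=year.astype(str))
        res = screen_fixed_effects(df, ["sex", "year"], "y")
        assert "sex" in res["significant"]
        ls = res["ls_means"].set_index(["factor", "level"])
        diff = ls.loc[("sex", "M"), "ls_mean"] - ls.loc[("sex", "F"), "ls_mean"]
        se = np.hypot(ls.loc[("sex", "M"), "se"], ls.loc[("sex", "F"), "se"])
        assert abs(diff - 0.22) < 2 * se

    def test_type_one_error_calibration_on_pure_noise(self):
        rng = np.random.default_rng(11)
        hits = 0
        trials = 60
        for _ in range(trials):
            n = 60
            df = rec_frame(
                y=rng.standard_normal(n),
                g=rng.choice(["a", "b", "c"], n),
            )
            res = screen_fixed_effects(df, ["g"], "y")
            hits += "g" in res["significant"]
        # expected ~5%; tolerate binomial noise
        assert hits / trials < 0.15

    def test_single_level_factor_rejected(self):
        df = rec_frame(y=[1.0, 2.0, 3.0], g=["a", "a", "a"])
        with pytest.raises(ValueError, match="fewer than two levels"):
            screen_fixed_effects(df, ["g"], "y")
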