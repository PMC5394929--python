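"""ANOVA battery against independent oracles; transforms; t/r statistics."""

import numpy as np
import pandas as pd
import pytest

from fxs_oscillo import (
    UndefinedValueError,
    ValidationError,
    factorial_anova,
    lsd_posthoc,
    maybe_log_transform,
    pearson,
    rm_anova,
    two_sample_t,
)
from helpers import brute_mixed_anova, random_mixed_table


class TestMaybeLogTransform:
    def test_symmetric_sample_unchanged(self):
        vals, applied = maybe_log_transform([1, 2, 3, 4, 5])
        assert not applied
        np.testing.assert_array_equal(vals, [1, 2, 3, 4, 5])

    def test_lognormal_sample_transformed(self, rng):
        x = rng.lognormal(mean=0.0, sigma=1.0, size=500)
        vals, applied = maybe_log_transform(x)
        assert applied
        np.testing.assert_allclose(vals, np.log10(x))

    def test_preregistered_measure_always_transformed(self):
        vals, applied = maybe_log_transform([1, 2, 3, 4, 5], "center_time_pct")
        assert applied

    def test_nonpositive_values_under_transform_rejected(self):
        with pytest.raises(ValidationError):
            maybe_log_transform([0.0, 1.0, 2.0], "wm_latency_s")


class TestFactorialAnova:
    @staticmethod
    def _table(counts, rng, effect=0.0):
        rows = []
        for (g, s), n in counts.items():
            for i in range(n):
                rows.append({"subject_id": f"{g}{s}{i}", "genotype": g, "sex": s,
                             "dose": "vehicle",
                             "y": rng.normal() + effect * (g == "KO")})
        return pd.DataFrame(rows)

    def test_df_den_is_n_minus_cells(self, rng):
        # 77 subjects across the 4 genotype × sex cells → error df 73
        counts = {("WT", "F"): 18, ("WT", "M"): 22, ("KO", "F"): 18, ("KO", "M"): 19}
        res = factorial_anova(self._table(counts, rng), "y")
        assert all(e.df_den == 73 for e in res.effects.values())

    def test_constant_data_gives_zero_f(self):
        df = self._table({("WT", "F"): 3, ("WT", "M"): 3,
                          ("KO", "F"): 3, ("KO", "M"): 3},
                         np.random.default_rng(0))
        df["y"] = 7.0
        res = factorial_anova(df, "y")
        for e in res.effects.values():
            assert e.F == 0.0 and e.p == 1.0

    def test_empty_cell_is_an_error(self, rng):
        df = self._table({("WT", "F"): 3, ("WT", "M"): 3, ("KO", "F"): 3}, rng)
        with pytest.raises(ValidationError, match="cell"):
            factorial_anova(df, "y")

    def test_matches_statsmodels_type2_on_unbalanced_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        for trial in range(10):
            counts = {cell: int(rng.integers(3, 9))
                      for cell in [("WT", "F"), ("WT", "M"), ("KO", "F"), ("KO", "M")]}
            df = self._table(counts, rng, effect=rng.normal())
            res = factorial_anova(df, "y")
            tab = sm.stats.anova_lm(smf.ols("y ~ C(genotype)*C(sex)", df).fit(),
                                    typ=2)
            pairs = [("genotype", "C(genotype)"), ("sex", "C(sex)"),
                     ("genotype:sex", "C(genotype):C(sex)")]
            for mine, theirs in pairs:
                assert res[mine].F == pytest.approx(tab.loc[theirs, "F"],
                                                    rel=1e-8)


class TestRmAnova:
    def test_reported_design_df_bookkeeping(self, rng):
        # 72 complete subjects in 4 groups × 4 doses: dose df (3, 204),
        # between df (1, 68)
        df = random_mixed_table(rng, n_per_cell=18)
        res = rm_anova(df, "y")
        assert (res["dose"].df_num, res["dose"].df_den) == (3, 204)
        assert (res["genotype"].df_num, res["genotype"].df_den) == (1, 68)
        assert res["dose:genotype"].df_den == 204

    def test_dose_invariant_data_gives_zero_dose_f(self, rng):
        df = random_mixed_table(rng, n_per_cell=3)
        df["y"] = df.groupby("subject_id")["y"].transform("mean")
        res = rm_anova(df, "y")
        assert res["dose"].F == 0.0

    def test_matches_brute_force_partition(self, rng):
        for trial in range(10):
            df = random_mixed_table(rng, n_per_cell=2,
                                    effects={"genotype": rng.normal(),
                                             "dose": rng.normal()})
            res = rm_anova(df, "y")
            oracle = brute_mixed_anova(df)
            for name, f_oracle in oracle.items():
                assert res[name].F == pytest.approx(f_oracle, rel=1e-8), name

    def test_incomplete_subjects_dropped(self, rng):
        df = random_mixed_table(rng, n_per_cell=3)
        df = df[~((df["subject_id"] == "WT-F-0") & (df["dose"] == "2.5"))]
        res = rm_anova(df, "y")
        assert res.design["dropped_subjects"] == ["WT-F-0"]
        assert res.design["n"] == 11

    def test_too_few_subjects_per_cell_is_an_error(self, rng):
        df = random_mixed_table(rng, n_per_cell=1)
        with pytest.raises(ValidationError, match="2 complete subjects"):
            rm_anova(df, "y")

    def test_single_within_level_reduces_to_factorial(self, rng):
        df = random_mixed_table(rng, n_per_cell=4, k=1)
        mixed = rm_anova(df, "y")
        fact = factorial_anova(df, "y", dose="vehicle")
        for name in ("genotype", "sex", "genotype:sex"):
            assert mixed[name].F == pytest.approx(fact[name].F, rel=1e-10)
            assert mixed[name].df_den == fact[name].df_den

    def test_sums_of_squares_partition_exactly(self, rng):
        df = random_mixed_table(rng, n_per_cell=3,
                                effects={"dose": 0.5, "genotype": 1.0})
        res = rm_anova(df, "y")
        y = df["y"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        ss_sum = (sum(e.ss for e in res.effects.values())
                  + res.strata["between"]["ss"] + res.strata["within"]["ss"])
        assert ss_sum == pytest.approx(ss_total, rel=1e-10)


class TestLsdPosthoc:
    def test_identical_means_give_t_zero(self, rng):
        df = random_mixed_table(rng, n_per_cell=3)
        df["y"] = df.groupby("subject_id")["y"].transform("mean")  # no dose effect
        res = rm_anova(df, "y")
        # add a within-stratum error so MS > 0 but keep means equal:
        ph = lsd_posthoc(res, "dose")
        assert all(ph.pairs["t"] == 0.0) and all(ph.pairs["p"] == 1.0)

    def test_pair_enumeration(self, rng):
        df = random_mixed_table(rng, n_per_cell=3)
        res = rm_anova(df, "y")
        assert len(lsd_posthoc(res, "dose")) == 6
        assert len(lsd_posthoc(res, "dose", reference="vehicle")) == 3

    def test_hand_computed_two_group_toy(self):
        # two groups, means 1 and 3, pooled MSE exactly 1 with df 8:
        # t = 2 / sqrt(1 * (1/5 + 1/5)) ≈ 3.162
        rows = []
        for g, m in (("WT", 1.0), ("KO", 3.0)):
            for i, off in enumerate([-1.0, -1.0, 0.0, 1.0, 1.0]):
                rows.append({"subject_id": f"{g}{i}", "genotype": g, "sex": "F",
                             "dose": "vehicle", "y": m + off})
        res = factorial_anova(pd.DataFrame(rows), "y", factors=("genotype",))
        ph = lsd_posthoc(res, "genotype")
        assert abs(ph.pairs.loc[0, "t"]) == pytest.approx(2.0 / np.sqrt(0.4),
                                                          rel=1e-9)
        assert ph.pairs.loc[0, "df"] == 8

    def test_unknown_reference_rejected(self, rng):
        df = random_mixed_table(rng, n_per_cell=3)
        res = rm_anova(df, "y")
        with pytest.raises(ValidationError):
            lsd_posthoc(res, "dose", reference="7.5")


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-30

    def test_orthogonal_vectors(self):
        res = pearson([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_r_to_p_mapping_at_reported_scale(self, rng):
        # r = −0.33 with n = 68 must map to p ≈ 0.006
        n, r_target = 68, -0.33
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = e - e @ x / (x @ x) * x
        e = (e - e.mean()) / e.std()
        y = r_target * x + np.sqrt(1 - r_target ** 2) * e
        res = pearson(x, y)
        assert res.r == pytest.approx(r_target, abs=1e-10)
        assert res.df == 66
        assert res.p == pytest.approx(0.006, abs=5e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_pooled_df_is_total_minus_two(self, rng):
        res = two_sample_t(rng.normal(size=33), rng.normal(size=35))
        assert res.df == 66

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [2.0, 3.0])
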