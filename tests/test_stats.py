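"""Factorial ANOVA layer: Type III two-way, mixed RM with GG correction,
Sidak and Tukey post-hoc adjustments."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from cagephys.stats import (
    FactorialAnova,
    anova_two_way,
    gg_epsilon,
    pairwise_sidak,
    rm_anova_gg,
    sidak_adjust,
    tukey_pairwise,
)


def lstsq_type3_oracle(df, dv, a_col, b_col):
    """Independent Type III computation: sum-to-zero coded cell-means model,
    each effect tested by full-vs-reduced model comparison via lstsq."""
    y = df[dv].to_numpy(dtype=float)
    a_levels = sorted(df[a_col].unique())
    b_levels = sorted(df[b_col].unique())
    a = np.where(df[a_col] == a_levels[0], 1.0, -1.0)
    b = np.where(df[b_col] == b_levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(y)), a, b, a * b])

    def ssr(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    full = ssr(X)
    dfe = len(y) - X.shape[1]
    out = {}
    for i, name in [(1, a_col), (2, b_col), (3, f"{a_col} x {b_col}")]:
        red = ssr(np.delete(X, i, axis=1))
        F = (red - full) / (full / dfe)
        out[name] = (F, float(sps.f.sf(F, 1, dfe)))
    return out


def unbalanced_2x2(seed=0, means=(0.5, 0.4, 0.3, 0.35), ns=(18, 19, 10, 11)):
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, geno), mu, n in zip(
        [("F", "c"), ("M", "c"), ("F", "m"), ("M", "m")], means, ns
    ):
        for _ in range(n):
            rows.append({"sex": sex, "geno": geno, "y": rng.normal(mu, 0.1)})
    return pd.DataFrame(rows)


class TestSidak:
    def test_single_comparison_identity(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_six_comparisons(self):
        assert sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99**6)

    def test_p_equal_one_stays_one(self):
        for m in (1, 3, 10):
            assert sidak_adjust(1.0, m) == 1.0

    def test_monotone_in_family_size(self):
        vals = [sidak_adjust(0.02, m) for m in range(1, 8)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_first_order_equals_bonferroni(self):
        p, m = 1e-6, 6
        assert sidak_adjust(p, m) == pytest.approx(p * m, rel=1e-3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.5, 2)


class TestTwoWayAnova:
    def test_null_cells_give_zero_F(self):
        # equal cell means, nonzero within-cell spread -> SS_effect = 0
        rows = []
        for sex in "FM":
            for geno in "cm":
                for d in (-1.0, 1.0):
                    rows.append({"sex": sex, "geno": geno, "y": 0.5 + d})
        res = anova_two_way(pd.DataFrame(rows), "y", ["sex", "geno"])
        for eff in ("sex", "geno", "sex x geno"):
            assert res.effect(eff)["F"] == pytest.approx(0.0, abs=1e-12)

    def test_additive_means_give_zero_interaction(self):
        rows = []
        for i, sex in enumerate("FM"):
            for j, geno in enumerate("cm"):
                mu = 0.3 + 0.1 * i + 0.2 * j  # purely additive
                for d in (-0.05, 0.05):
                    rows.append({"sex": sex, "geno": geno, "y": mu + d})
        res = anova_two_way(pd.DataFrame(rows), "y", ["sex", "geno"])
        assert res.effect("sex x geno")["F"] == pytest.approx(0.0, abs=1e-10)
        assert res.effect("geno")["F"] > 10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unbalanced_type3_matches_cell_means_oracle(self, seed):
        df = unbalanced_2x2(seed)
        res = anova_two_way(df, "y", ["sex", "geno"])
        oracle = lstsq_type3_oracle(df, "y", "sex", "geno")
        for eff, (F, p) in oracle.items():
            assert res.effect(eff)["F"] == pytest.approx(F, abs=1e-8)
            assert res.effect(eff)["p"] == pytest.approx(p, abs=1e-8)
        assert res.effect("sex")["df2"] == len(df) - 4

    def test_empty_cell_rejected(self):
        df = unbalanced_2x2()
        df = df[~((df["sex"] == "F") & (df["geno"] == "m"))]
        with pytest.raises(ValueError):
            anova_two_way(df, "y", ["sex", "geno"])

    def test_zero_error_df_rejected(self):
        rows = [
            {"sex": s, "geno": g, "y": 0.1} for s in "FM" for g in "cm"
        ]
        with pytest.raises(ValueError):
            anova_two_way(pd.DataFrame(rows), "y", ["sex", "geno"])


def mixed_frame(seed=1, k=3, ns=(18, 19), slopes=(0.05, 0.025), noise=0.04):
    rng = np.random.default_rng(seed)
    rows, sid = [], 0
    for g, n, sl in zip("AB", ns, slopes):
        for _ in range(n):
            sid += 1
            base = rng.normal(0.3, 0.05)
            for day in range(k):
                rows.append(
                    {
                        "subj": f"s{sid}",
                        "grp": g,
                        "day": day + 1,
                        "y": base + sl * day + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedRmAnova:
    def test_matches_pingouin_F_values(self):
        df = mixed_frame()
        res = rm_anova_gg(df, "y", between="grp", within="day", subject="subj")
        aov = pg.mixed_anova(
            df, dv="y", within="day", subject="subj", between="grp", correction=True
        ).set_index("Source")
        assert res.effect("grp")["F"] == pytest.approx(aov.loc["grp", "F"], rel=1e-9)
        assert res.effect("day")["F"] == pytest.approx(aov.loc["day", "F"], rel=1e-9)
        assert res.effect("day x grp")["F"] == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9
        )

    def test_two_level_within_gives_epsilon_one(self):
        df = mixed_frame(k=2)
        res = rm_anova_gg(df, "y", between="grp", within="day", subject="subj")
        assert res.epsilon == pytest.approx(1.0)
        assert res.effect("day")["df1"] == pytest.approx(1.0)

    def test_epsilon_lower_bound(self):
        # maximally non-spherical: one level carries all the variance
        rng = np.random.default_rng(3)
        k = 4
        x = np.zeros((12, k))
        x[:, 0] = rng.normal(0, 5, 12)
        x += rng.normal(0, 1e-3, x.shape)
        eps = gg_epsilon(x)
        assert eps >= 1.0 / (k - 1) - 1e-12
        assert eps < 0.5

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(4)
        n, k = 400, 4
        subj = rng.normal(0, 1.0, (n, 1))
        x = subj + rng.normal(0, 0.5, (n, k))  # exchangeable covariance
        assert gg_epsilon(x) > 0.97

    def test_epsilon_matches_pingouin_on_ungrouped_data(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(25, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        mine = gg_epsilon(x)
        ref = float(pg.epsilon(pd.DataFrame(x), correction="gg"))
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_gg_never_equals_uncorrected_df(self):
        df = mixed_frame()
        corr = rm_anova_gg(df, "y", between="grp", within="day", subject="subj")
        raw = rm_anova_gg(df, "y", between="grp", within="day", subject="subj", gg="never")
        assert raw.effect("day")["df1"] == 2.0
        assert corr.effect("day")["df1"] == pytest.approx(2 * corr.epsilon)
        assert corr.effect("day")["F"] == pytest.approx(raw.effect("day")["F"])
        if corr.epsilon < 1:
            assert corr.effect("day")["p"] > raw.effect("day")["p"]

    def test_incomplete_subject_dropped_listwise(self):
        df = mixed_frame()
        df = df.drop(df[(df["subj"] == "s1") & (df["day"] == 3)].index)
        res = rm_anova_gg(df, "y", between="grp", within="day", subject="subj")
        assert "s1" not in set(res.model.data["subj"])
        assert res.effect("grp")["df2"] == 36 - 2  # 36 complete subjects, 2 groups

    def test_fractional_df_reporting(self):
        df = mixed_frame(seed=7, k=3, noise=0.08)
        res = rm_anova_gg(df, "y", between="grp", within="day", subject="subj")
        row = res.effect("day")
        if res.epsilon < 1:
            assert row["df1"] != round(row["df1"]) or row["df2"] != round(row["df2"])
        assert "Greenhouse" in res.summary()


class TestPosthoc:
    def test_identical_groups_tukey_p_near_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 40)
        vals = np.concatenate([v, v])
        groups = ["a"] * 40 + ["b"] * 40
        out = tukey_pairwise(vals, groups)
        assert out["p_adj"].iloc[0] > 0.99

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(1)
        data = [rng.normal(m, 1, 12) for m in (0.0, 0.5, 1.0, 0.2)]
        vals = np.concatenate(data)
        groups = sum([[f"g{i}"] * 12 for i in range(4)], [])
        mine = tukey_pairwise(vals, groups).set_index(["group_a", "group_b"])
        ref = sps.tukey_hsd(*data)
        for i in range(4):
            for j in range(i + 1, 4):
                assert mine.loc[(f"g{i}", f"g{j}")]["p_adj"] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-6
                )

    def test_tukey_p_not_below_pooled_t_test(self):
        """With the same pooled MS error and df, the studentized-range p can
        never undercut the unadjusted pairwise t-test p."""
        rng = np.random.default_rng(2)
        for rep in range(10):
            data = [rng.normal(rng.normal(0, 0.3), 1, 10) for _ in range(4)]
            vals = np.concatenate(data)
            groups = sum([[f"g{i}"] * 10 for i in range(4)], [])
            tuk = tukey_pairwise(vals, groups).set_index(["group_a", "group_b"])
            mse = np.mean([np.var(d, ddof=1) for d in data])
            df_err = 4 * (10 - 1)
            for i in range(4):
                for j in range(i + 1, 4):
                    t = (data[i].mean() - data[j].mean()) / np.sqrt(mse * 2 / 10)
                    p = 2 * sps.t.sf(abs(t), df_err)
                    assert tuk.loc[(f"g{i}", f"g{j}")]["p_adj"] >= p - 1e-9

    def test_sidak_family_is_explicit(self):
        df = unbalanced_2x2()
        vals, groups = df["y"].to_numpy(), (df["sex"] + ":" + df["geno"]).to_numpy()
        all_pairs = pairwise_sidak(vals, groups)
        assert len(all_pairs) == 6
        one = pairwise_sidak(vals, groups, pairs=[("F:c", "M:c")], family_size=6)
        both = all_pairs.set_index(["group_a", "group_b"])
        assert one["p_adj"].iloc[0] == pytest.approx(
            both.loc[("F:c", "M:c")]["p_adj"]
        )
        assert (all_pairs["p_adj"] >= all_pairs["p_raw"] - 1e-12).all()

    def test_results_object_pairwise_access(self):
        df = unbalanced_2x2()
        res = anova_two_way(df, "y", ["sex", "geno"])
        out = res.pairwise(method="sidak")
        assert {"group_a", "group_b", "p_adj"} <= set(out.columns)
        out_t = res.pairwise(method="tukey")
        assert len(out_t) == 6
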