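import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from discdegen.stats import (
    LongTable,
    correlate,
    friedman,
    kruskal_wallis,
    posthoc,
    rm_anova_two_way,
)


def make_table(y, subjects, a_levels, b_levels):
    rows = []
    i = 0
    for s in range(subjects):
        for a in range(a_levels):
            for b in range(b_levels):
                rows.append({"subj": s, "A": f"a{a}", "B": f"b{b}", "y": y[i]})
                i += 1
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_null_data_gives_zero_f(self):
        df = make_table(np.full(12, 3.0), 3, 2, 2)
        res = rm_anova_two_way(df, dv="y", subject="subj", factors=("A", "B"))
        assert res.degenerate
        for eff in res.statistic.values():
            assert eff == 0.0

    def test_pure_treatment_shift(self, rng):
        rows = []
        for s in range(6):
            base = rng.normal()
            for a in range(3):
                for b in range(4):
                    rows.append({"subj": s, "A": a, "B": b, "y": base + 5.0 * a})
        res = rm_anova_two_way(pd.DataFrame(rows), dv="y", subject="subj", factors=("A", "B"))
        assert res.p_value["A"] < 1e-10
        assert res.statistic["B"] == 0.0
        assert res.p_value["B"] == 1.0

    def test_hand_sum_of_squares_oracle(self):
        # 3 subjects x 2 x 2, worked independently below from cell means
        y = np.array([[[4.1, 6.3], [5.2, 9.0]],
                      [[3.4, 5.1], [4.7, 8.2]],
                      [[5.6, 8.8], [6.9, 12.4]]])  # [subj, A, B]
        n = a = b = None
        n, a, b = y.shape
        gm = y.mean()
        ss_a = n * b * ((y.mean(axis=(0, 2)) - gm) ** 2).sum()
        ss_b = n * a * ((y.mean(axis=(0, 1)) - gm) ** 2).sum()
        ab = y.mean(axis=0)
        ss_ab = n * ((ab - y.mean(axis=(0, 2))[:, None] - y.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        as_ = y.mean(axis=2)
        ss_as = b * ((as_ - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + gm) ** 2).sum()
        bs = y.mean(axis=1)
        ss_bs = a * ((bs - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        ss_s = a * b * ((y.mean(axis=(1, 2)) - gm) ** 2).sum()
        ss_abs = ((y - gm) ** 2).sum() - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs
        f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
        f_ab = (ss_ab / 1) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))

        df = make_table(y.reshape(-1), 3, 2, 2)
        res = rm_anova_two_way(df, dv="y", subject="subj", factors=("A", "B"))
        assert res.statistic["A"] == pytest.approx(f_a)
        assert res.statistic["B"] == pytest.approx(f_b)
        assert res.statistic["A*B"] == pytest.approx(f_ab)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for s in range(6):
            for a in range(3):
                for b in range(4):
                    rows.append(
                        {"subj": s, "A": f"a{a}", "B": f"b{b}",
                         "y": rng.normal() + 0.5 * a + 0.2 * b}
                    )
        df = pd.DataFrame(rows)
        mine = rm_anova_two_way(df, dv="y", subject="subj", factors=("A", "B"))
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj", detailed=True)
        for src, eff in (("A", "A"), ("B", "B"), ("A * B", "A*B")):
            row = ref[ref["Source"] == src].iloc[0]
            assert mine.statistic[eff] == pytest.approx(row["F"], rel=1e-9)
            assert mine.p_value[eff] == pytest.approx(row["p_unc"], rel=1e-9)

    def test_missing_cells_reported(self):
        df = make_table(np.arange(12.0), 3, 2, 2)
        df = df.drop(index=5)
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_two_way(df, dv="y", subject="subj", factors=("A", "B"))

    def test_longtable_roles(self):
        df = make_table(np.arange(12.0), 3, 2, 2)
        lt = LongTable(df, subject="subj", response="y", within=("A", "B"))
        assert lt.balanced
        res = rm_anova_two_way(lt)
        assert set(res.statistic) == {"A", "B", "A*B"}
        with pytest.raises(ValueError, match="unique"):
            LongTable(pd.concat([df, df]), subject="subj", response="y", within=("A", "B"))


class TestPosthoc:
    def test_two_groups_single_comparison(self, rng):
        df = pd.DataFrame({"g": ["x"] * 8 + ["y"] * 8, "v": rng.normal(size=16)})
        tab = posthoc(df, dv="v", group="g", method="bonferroni")
        assert len(tab) == 1
        assert tab["p_adjusted"].iloc[0] == pytest.approx(tab["p_raw"].iloc[0])

    def test_four_groups_six_comparisons(self, rng):
        df = pd.DataFrame(
            {"g": np.repeat(list("abcd"), 6), "v": rng.normal(size=24)}
        )
        tab = posthoc(df, dv="v", group="g", method="bonferroni")
        assert len(tab) == 6
        np.testing.assert_allclose(
            tab["p_adjusted"], np.minimum(1.0, 6 * tab["p_raw"]), rtol=1e-12
        )
        assert (tab["p_adjusted"] >= tab["p_raw"] - 1e-15).all()

    def test_tukey_matches_scipy_reference(self, rng):
        groups = [rng.normal(loc=m, size=7) for m in (0.0, 0.5, 2.0)]
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 7), "v": np.concatenate(groups)}
        )
        tab = posthoc(df, dv="v", group="g", method="tukey_hsd")
        ref = sps.tukey_hsd(*groups)
        got = {(r["group_a"], r["group_b"]): r["p_adjusted"] for _, r in tab.iterrows()}
        assert got[("a", "b")] == pytest.approx(ref.pvalue[0, 1])
        assert got[("b", "c")] == pytest.approx(ref.pvalue[1, 2])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": ["only"] * 5, "v": range(5)})
        with pytest.raises(ValueError):
            posthoc(df, dv="v", group="g")


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([np.ones(5), np.ones(5)])
        assert res.degenerate
        assert res.statistic["H"] == 0.0
        assert res.p_value["H"] == 1.0

    def test_fully_separated_groups(self):
        res = kruskal_wallis([np.array([1.0, 2.0]), np.array([10.0, 11.0]),
                              np.array([20.0, 21.0])])
        # maximal separation for these sizes; matches scipy's H
        ref = sps.kruskal([1.0, 2.0], [10.0, 11.0], [20.0, 21.0])
        assert res.statistic["H"] == pytest.approx(ref.statistic)
        assert res.p_value["H"] == pytest.approx(ref.pvalue)
        # H is maximal: equal to H on perfectly separated rank blocks
        sep = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                              np.array([5.0, 6.0])])
        assert res.statistic["H"] == pytest.approx(sep.statistic["H"])
        assert res.p_value["H"] < 0.15

    def test_statistic_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 4, size=8).astype(float) for _ in range(3)]
        ref = sps.kruskal(*groups)
        res = kruskal_wallis(groups)
        assert res.statistic["H"] == pytest.approx(ref.statistic, rel=1e-12)

    def test_exact_p_matches_enumeration_oracle(self):
        g1 = np.array([1.2, 3.4, 2.2, 5.1])
        g2 = np.array([4.4, 6.1, 5.9, 7.0])
        res = kruskal_wallis([g1, g2], p_method="exact")
        ranks = sps.rankdata(np.concatenate([g1, g2]))
        n = 8

        def h(r1, r2):
            return 12 / (n * (n + 1)) * (
                4 * (np.mean(r1) - 4.5) ** 2 + 4 * (np.mean(r2) - 4.5) ** 2
            )

        hobs = h(ranks[:4], ranks[4:])
        hits = total = 0
        for c in itertools.combinations(range(n), 4):
            rest = [i for i in range(n) if i not in c]
            total += 1
            hits += h(ranks[list(c)], ranks[rest]) >= hobs - 1e-12
        assert res.p_value["H"] == pytest.approx(hits / total)
        assert res.statistic["H"] == pytest.approx(hobs)

    def test_invariant_to_monotone_transform(self, rng):
        groups = [rng.normal(size=6) + m for m in (0, 1, 2)]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in groups])
        assert res1.statistic["H"] == pytest.approx(res2.statistic["H"])


class TestFriedman:
    def test_identical_permutation_rows_match_hand_ranking(self):
        # each block ranks the three conditions 1 < 2 < 3 identically:
        # rank sums are 4, 8, 12 -> chi2 = 12/(4*3*4) * ((4-8)^2+0+(12-8)^2) = 8
        y = np.array([[1.0, 5.0, 9.0],
                      [2.0, 4.0, 9.0],
                      [1.0, 6.0, 7.0],
                      [3.0, 5.0, 8.0]])
        res = friedman(y)
        assert res.statistic["chi2"] == pytest.approx(8.0)
        ref = sps.friedmanchisquare(*y.T)
        assert res.statistic["chi2"] == pytest.approx(ref.statistic)
        assert res.p_value["chi2"] == pytest.approx(ref.pvalue)

    def test_tied_blocks_degenerate(self):
        res = friedman(np.ones((4, 3)))
        assert res.degenerate
        assert res.p_value["chi2"] == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        y = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]])
        res = friedman(y, p_method="exact")
        # oracle: enumerate all within-block orderings of the observed ranks
        ranks = np.apply_along_axis(sps.rankdata, 1, y)
        n, k = ranks.shape

        def chi(r):
            col = r.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * np.sum((col - n * (k + 1) / 2) ** 2)

        obs = chi(ranks)
        perms = list(itertools.permutations(range(k)))
        hits = total = 0
        for combo in itertools.product(perms, repeat=n):
            r = np.vstack([ranks[i, list(combo[i])] for i in range(n)])
            total += 1
            hits += chi(r) >= obs - 1e-12
        assert res.p_value["chi2"] == pytest.approx(hits / total)

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.normal(size=(6, 4))
        assert friedman(y).statistic["chi2"] == pytest.approx(
            friedman(np.tanh(y)).statistic["chi2"]
        )


class TestCorrelate:
    def test_perfect_negative_line_both_methods(self):
        x = np.arange(10.0)
        y = -2.0 * x + 5.0
        for method in ("pearson", "spearman"):
            r, p = correlate(x, y, method)
            assert r == pytest.approx(-1.0)
            assert p < 1e-6

    def test_three_point_line(self):
        r, _ = correlate([1.0, 2.0, 3.0], [6.0, 4.0, 2.0], "pearson")
        assert r == pytest.approx(-1.0)

    def test_independent_permutation_near_zero(self, rng):
        x = rng.normal(size=500)
        y = rng.permutation(x)
        r, _ = correlate(x, y, "pearson")
        assert abs(r) < 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_values_in_unit_interval(self, rng):
        for _ in range(5):
            _, p = correlate(rng.normal(size=10), rng.normal(size=10))
            assert 0.0 <= p <= 1.0
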