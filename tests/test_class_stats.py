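import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smoltqg.class_stats import (
    anova_by_class,
    classify_and_score,
    correlation_matrix,
    fit_dfa,
    tukey_kramer,
)


def _classes(rng, means, n_per=30, sd=1.0):
    rows = []
    for cls, m in means.items():
        for v in rng.normal(m, sd, n_per):
            rows.append((cls, v))
    return pd.DataFrame(rows, columns=["life_history", "y"])


class TestANOVA:
    def test_textbook_two_group_fixture(self):
        # hand-computed one-way ANOVA: groups {1,2,3,4} and {3,4,5,6}
        df = pd.DataFrame({
            "life_history": ["a"] * 4 + ["b"] * 4,
            "y": [1.0, 2, 3, 4, 3, 4, 5, 6],
        })
        t = anova_by_class(df, "y")
        # SSB = 8, MSW = 5/3; F = 8 / (5/3) = 4.8
        assert t.statistic == pytest.approx(4.8)
        assert t.p_value == pytest.approx(stats.f.sf(4.8, 1, 6))

    def test_separated_classes_reject(self, rng):
        df = _classes(rng, {"mature": 0, "parr": 3, "smolt": 6, "indeterminate": 9})
        assert anova_by_class(df, "y").p_value < 1e-4

    def test_single_class_errors(self, rng):
        df = _classes(rng, {"smolt": 0.0})
        with pytest.raises(ValueError):
            anova_by_class(df, "y")


class TestTukeyKramer:
    def test_two_groups_reduce_to_t_test(self, rng):
        df = _classes(rng, {"a": 0.0, "b": 0.4}, n_per=25)
        res = tukey_kramer(df, "y")
        t = stats.ttest_ind(df[df.life_history == "a"]["y"], df[df.life_history == "b"]["y"])
        assert res["p_adj"][0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_outlying_class_only_its_comparisons(self, rng):
        df = _classes(rng, {"a": 0.0, "b": 0.0, "c": 0.0, "d": 5.0}, n_per=40)
        res = tukey_kramer(df, "y")
        has_d = res["group1"].eq("d") | res["group2"].eq("d")
        assert res.loc[has_d, "reject"].all()
        assert not res.loc[~has_d, "reject"].any()

    def test_null_familywise_control(self, rng):
        clean = 0
        for _ in range(50):
            df = _classes(rng, {"a": 0, "b": 0, "c": 0, "d": 0}, n_per=15)
            res = tukey_kramer(df, "y")
            clean += not res["reject"].any()
        assert clean >= 44  # ~95% of null replicates have no rejections


class TestCorrelations:
    def test_perfect_copy_and_pair_count(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        df["a2"] = df["a"]
        cm = correlation_matrix(df, ["a", "a2", "b", "c", "d"])
        assert cm.estimates.loc["a", "a2"] == pytest.approx(1.0)
        assert cm.n_pairs() == 10
        E = cm.estimates.to_numpy()
        assert np.allclose(E, E.T, equal_nan=True)
        assert np.allclose(np.diag(E), 1.0)

    def test_22_traits_gives_231_pairs(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 22)),
                          columns=[f"t{i}" for i in range(22)])
        cm = correlation_matrix(df, list(df.columns))
        assert cm.n_pairs() == 231

    def test_null_rate_and_alpha_monotonicity(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 22)),
                          columns=[f"t{i}" for i in range(22)])
        cm = correlation_matrix(df, list(df.columns))
        n05 = cm.n_significant(0.05)
        assert 2 <= n05 <= 26  # ~5% of 231 under independence
        assert cm.n_significant(0.01) <= n05
        assert cm.n_significant(0.001) <= cm.n_significant(0.01)

    def test_spearman_for_binary_pairs(self, rng):
        df = pd.DataFrame({
            "LHSmolt": rng.integers(0, 2, 100).astype(float),
            "len": rng.normal(size=100),
        })
        cm = correlation_matrix(df, ["LHSmolt", "len"])
        assert cm.methods.loc["LHSmolt", "len"] == "spearman"

    def test_constant_column_warns_missing_cell(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(df, ["a", "b"])
        assert np.isnan(cm.estimates.loc["a", "b"])


class TestDFA:
    def _separable(self, rng, n=60):
        X1 = rng.normal([0, 0], 0.3, (n, 2))
        X2 = rng.normal([5, 0], 0.3, (n, 2))
        X3 = rng.normal([0, 5], 0.3, (n, 2))
        X4 = rng.normal([5, 5], 0.3, (n, 2))
        df = pd.DataFrame(np.vstack([X1, X2, X3, X4]), columns=["u", "v"])
        df["life_history"] = np.repeat(["mature", "parr", "indeterminate", "smolt"], n)
        return df

    def test_separable_resubstitution_100(self, rng):
        df = self._separable(rng)
        model = fit_dfa(df, ["u", "v"])
        _, acc, conf = classify_and_score(model, df)
        assert acc == 100.0
        assert int(np.diag(conf.to_numpy()).sum()) == len(df)

    def test_identical_distributions_chance_level(self, rng):
        n = (400, 100, 100, 100)  # largest prior = 4/7
        rows = []
        for cls, k in zip(["smolt", "parr", "mature", "indeterminate"], n):
            for _ in range(k):
                rows.append((cls, rng.normal(), rng.normal()))
        df = pd.DataFrame(rows, columns=["life_history", "u", "v"])
        model = fit_dfa(df, ["u", "v"])
        _, acc, _ = classify_and_score(model, df)
        assert acc == pytest.approx(100 * 400 / 700, abs=6.0)

    def test_two_class_boundary_at_midpoint(self, rng):
        # equal-variance, equal-priors one-dimensional problem: the Bayes
        # boundary is the midpoint of the class means
        n = 4000
        df = pd.DataFrame({
            "x": np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)],
            "life_history": np.repeat(["a", "b"], n),
        })
        model = fit_dfa(df, ["x"])
        xs = np.linspace(0.5, 1.5, 2001)
        grid = pd.DataFrame({"x": xs, "life_history": "a"})
        pred, _, _ = classify_and_score(model, grid)
        lab = pred["predicted"].to_numpy()
        j = int(np.where((lab[:-1] == "a") & (lab[1:] == "b"))[0][0])
        boundary = 0.5 * (xs[j] + xs[j + 1])
        # empirical midpoint of the two class means
        mid = 0.5 * (df[df.life_history == "a"]["x"].mean()
                     + df[df.life_history == "b"]["x"].mean())
        assert boundary == pytest.approx(mid, abs=0.01)

    def test_affine_invariance(self, rng):
        df = self._separable(rng)
        model = fit_dfa(df, ["u", "v"])
        _, acc, _ = classify_and_score(model, df)
        df2 = df.copy()
        df2["u"] = 100.0 * df2["u"] - 40.0
        model2 = fit_dfa(df2, ["u", "v"])
        _, acc2, _ = classify_and_score(model2, df2)
        assert acc == pytest.approx(acc2, abs=1e-9)

    def test_permuted_labels_chance(self, rng):
        df = self._separable(rng)
        df["life_history"] = rng.permutation(df["life_history"].to_numpy())
        model = fit_dfa(df, ["u", "v"])
        _, acc, _ = classify_and_score(model, df)
        assert acc < 40.0  # 4 balanced classes: chance is 25%

    def test_small_class_errors(self, rng):
        df = self._separable(rng, n=2)
        with pytest.raises(ValueError, match="fewer cases"):
            fit_dfa(df, ["u", "v"])
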