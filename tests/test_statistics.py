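"""Tests for the statistical layer: t-tests, Tukey–Kramer + letters,
Pearson matrices and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import seedvigor as sv
from seedvigor.statistics import DegenerateDesignError, InvalidInputError


def t_stat_oracle(a, b):
    """Independent pooled-variance t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
        a.size + b.size - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))


class TestTTests:
    def test_clear_separation_flagged(self):
        res = sv.t_test_vs_control(
            {"CTRL": [2.1, 2.2, 2.3], "HP": [1.1, 1.2, 1.3]}, "CTRL")
        row = res.iloc[0]
        assert row["significant"]
        assert row["t"] == pytest.approx(t_stat_oracle([1.1, 1.2, 1.3],
                                                       [2.1, 2.2, 2.3]))

    def test_identical_constant_groups_not_flagged(self):
        res = sv.t_test_vs_control({"CTRL": [1.0, 1.0], "X": [1.0, 1.0]}, "CTRL")
        assert not res.iloc[0]["significant"]
        assert res.iloc[0]["p"] == 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(InvalidInputError):
            sv.t_test_vs_control({"CTRL": [1.0, 2.0], "X": [1.0]}, "CTRL")


class TestTukeyKramer:
    def test_matches_statsmodels_oracle_unequal_n(self):
        rng = np.random.default_rng(11)
        groups = {"A": rng.normal(0, 1, 4), "B": rng.normal(1, 1, 6),
                  "C": rng.normal(3, 1, 5)}
        ours = sv.tukey_kramer(groups).set_index(["group1", "group2"])
        flat = np.concatenate(list(groups.values()))
        labels = sum([[g] * len(v) for g, v in groups.items()], [])
        sm_res = pairwise_tukeyhsd(flat, labels, alpha=0.05)
        sm_table = pd.DataFrame(sm_res._results_table.data[1:],
                                columns=sm_res._results_table.data[0])
        for _, row in sm_table.iterrows():
            mine = ours.loc[(row["group1"], row["group2"])]
            assert mine["p_adj"] == pytest.approx(float(row["p-adj"]), abs=1e-3)
            assert bool(mine["reject"]) == bool(row["reject"])

    def test_well_separated_groups_all_reject(self):
        groups = {"A": [0.0, 0.1, -0.1], "B": [10.0, 10.1, 9.9],
                  "C": [20.0, 20.1, 19.9]}
        pw = sv.tukey_kramer(groups)
        assert pw["reject"].all()


class TestLetters:
    def test_identical_groups_share_single_letter(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 5)
        groups = {g: base + rng.normal(0, 0.01, 5) for g in "ABC"}
        pw = sv.tukey_kramer(groups)
        letters = sv.compact_letter_display(
            pw, {g: float(np.mean(v)) for g, v in groups.items()})
        assert {ld.letters for ld in letters} == {"a"}

    def test_outlier_group_gets_own_letter(self):
        groups = {"A": [0.0, 0.1, -0.1], "B": [0.05, 0.0, 0.1],
                  "C": [10.0, 10.1, 9.9]}
        pw = sv.tukey_kramer(groups)
        letters = {ld.group: ld.letters
                   for ld in sv.compact_letter_display(
                       pw, {g: float(np.mean(v)) for g, v in groups.items()})}
        assert letters["C"] != letters["A"]
        assert letters["A"] == letters["B"]
        assert len(set(letters.values())) == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_share_letter_iff_nonsignificant(self, seed):
        """The compact-letter-display biconditional on randomized inputs."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = {f"g{i}": rng.normal(rng.uniform(0, 4), 1.0,
                                      int(rng.integers(3, 7)))
                  for i in range(k)}
        pw = sv.tukey_kramer(groups)
        letters = {ld.group: set(ld.letters)
                   for ld in sv.compact_letter_display(
                       pw, {g: float(np.mean(v)) for g, v in groups.items()})}
        for _, row in pw.iterrows():
            shares = bool(letters[row["group1"]] & letters[row["group2"]])
            assert shares == (not row["reject"])


class TestAnova:
    @staticmethod
    def balanced_layout(rng, effect_a=0.0, effect_b=0.0, interaction=0.0,
                        n_per_cell=3):
        rows = []
        for i, a in enumerate(("a1", "a2", "a3")):
            for j, b in enumerate(("b1", "b2")):
                mu = effect_a * i + effect_b * j + interaction * i * j
                for _ in range(n_per_cell):
                    rows.append({"A": a, "B": b, "y": mu + rng.normal()})
        return pd.DataFrame(rows)

    def test_strong_main_effect_detected(self):
        rng = np.random.default_rng(0)
        df = self.balanced_layout(rng, effect_a=5.0)
        anova, pw, letters = sv.anova_tukey_kramer(df, "y", ["A", "B"])
        assert anova.loc["A", "PR(>F)"] < 1e-6
        assert letters[0].letters != letters[-1].letters

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(0)
        df = self.balanced_layout(rng)
        df = df[~((df["A"] == "a1") & (df["B"] == "b2"))]
        with pytest.raises(DegenerateDesignError):
            sv.anova_tukey_kramer(df, "y", ["A", "B"])

    def test_one_factor_reduces_to_oneway(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"A": ["a"] * 4 + ["b"] * 4,
                           "y": np.r_[rng.normal(0, 1, 4), rng.normal(4, 1, 4)]})
        anova, pw, letters = sv.anova_tukey_kramer(df, "y", ["A"])
        assert anova.loc["A", "PR(>F)"] < 0.01
        assert len(pw) == 1


class TestPearson:
    def test_diagonal_and_perfect_anticorrelation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -2 * x, "z": np.r_[x[:-1], 5.0]})
        r, p = sv.pearson_matrix(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-10

    def test_simulated_known_correlation(self):
        rng = np.random.default_rng(8)
        n, rho = 100, 0.8
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        df = pd.DataFrame(xy, columns=["x", "y"])
        r, _ = sv.pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(rho, abs=0.1)

    def test_zero_variance_column_is_nan(self, caplog):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        with caplog.at_level("WARNING"):
            r, p = sv.pearson_matrix(df)
        assert np.isnan(r.loc["x", "c"])
        assert any("zero variance" in m for m in caplog.messages)

    def test_pairwise_complete(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan],
                           "y": [2.0, 4, 6, 8, 100],
                           "z": [1.0, 1, 2, 3, 5]})
        r, _ = sv.pearson_matrix(df)
        # the NaN row is excluded for (x, y) so the pair is perfectly linear
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        """KS check: p-values of independent columns are uniform."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
            _, p = sv.pearson_matrix(df)
            pvals.append(p.loc["a", "b"])
        from scipy import stats as sps
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": 3 * x + 1})
        res = sv.pca(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        res = sv.pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        sk = SkPCA().fit(Z.to_numpy())
        assert res.explained_variance_ratio == pytest.approx(
            sk.explained_variance_ratio_, abs=1e-10)
        assert np.abs(res.scores.to_numpy()) == pytest.approx(
            np.abs(sk.transform(Z.to_numpy())), abs=1e-8)

    def test_variance_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        res = sv.pca(df, columns=list(df.columns))
        evr = res.explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))

    def test_scores_preserve_distances(self):
        """All components retained: score distances equal z-space distances."""
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(15, 4)))
        df.columns = [str(c) for c in df.columns]
        res = sv.pca(df, columns=list(df.columns))
        Z = (df - df.mean()) / df.std(ddof=1)
        assert pdist(res.scores.to_numpy()) == pytest.approx(
            pdist(Z.to_numpy()), abs=1e-8)

    def test_constant_column_dropped(self, caplog):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                           "c": np.ones(10)})
        with caplog.at_level("WARNING"):
            res = sv.pca(df)
        assert res.dropped_columns == ("c",)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        r1, r2 = sv.pca(df), sv.pca(df)
        assert (r1.loadings == r2.loadings).all().all()
        for pc in r1.loadings.columns:
            col = r1.loadings[pc]
            assert col.loc[col.abs().idxmax()] > 0
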