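"""Distances, clustering, PERMANOVA and nonparametric tests.

The from-scratch implementations are checked against independent oracles:
scipy's pairwise Bray-Curtis and average linkage, scikit-bio's PERMANOVA,
classical ANOVA, and brute-force enumeration.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

import dietstat as ds
from dietstat.community_stats import _oneway_ss
from dietstat.errors import ValidationError


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [chr(65 + i) for i in range(len(values))]
    return ds.DistanceMatrix(ids=ids, values=values)


class TestFourthRoot:
    def test_values(self):
        out = ds.fourth_root(np.array([[16.0, 0.0, 81.0]]))
        assert np.allclose(out, [[2.0, 0.0, 3.0]])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            ds.fourth_root(np.array([-1.0]))


class TestBrayCurtis:
    def test_disjoint_identical_and_hand_value(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [1.0, 3.0]])
        D = ds.bray_curtis(X).values
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 2] == pytest.approx(0.0)
        assert D[3, 4] == pytest.approx(0.25)  # (1+1)/8

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            X = rng.gamma(1, 1, (8, 5)) * (rng.random((8, 5)) < 0.8)
            mine = ds.bray_curtis(X).values
            ref = squareform(pdist(X, metric="braycurtis"))
            assert np.allclose(mine, ref, atol=1e-12)

    def test_metric_axioms_on_random_data(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            X = rng.gamma(1, 1, (6, 4))
            D = ds.bray_curtis(X).values
            assert np.allclose(D, D.T, atol=1e-12)
            assert np.allclose(np.diag(D), 0)
            assert D.min() >= 0 and D.max() <= 1 + 1e-12

    def test_all_zero_pair_warns_and_is_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            D = ds.bray_curtis(X).values
        assert D[0, 1] == 0.0


class TestUpgma:
    def test_three_leaf_hand_example(self):
        D = _dm([[0, 2, 6], [2, 0, 8], [6, 8, 0]])
        tree = ds.upgma(D)
        assert tree.merges[0, 2] == pytest.approx(2.0)
        assert tree.merges[1, 2] == pytest.approx(7.0)  # (6 + 8) / 2

    def test_newick_of_hand_example(self):
        D = _dm([[0, 2, 6], [2, 0, 8], [6, 8, 0]])
        assert ds.to_newick(ds.upgma(D)) == "((A:1.0,B:1.0):2.5,C:3.5);"

    def test_two_leaves(self):
        assert ds.to_newick(ds.upgma(_dm([[0, 3], [3, 0]]))) == "(A:1.5,B:1.5);"

    def test_newick_round_trip_preserves_leaf_distances(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(1, 1, (6, 4))
        D = ds.bray_curtis(X)
        tree = ds.upgma(D)
        import io
        from skbio import TreeNode

        parsed = TreeNode.read(io.StringIO(ds.to_newick(tree)))
        # leaf-to-leaf path length equals the merge height of their junction
        heights = _cophenetic(tree)
        for a, b in itertools.combinations(D.ids, 2):
            assert parsed.find(a).distance(parsed.find(b)) == pytest.approx(
                heights[(a, b)], abs=1e-9
            )

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            X = rng.gamma(1, 1, (8, 5))
            D = ds.bray_curtis(X)
            mine = np.sort(ds.upgma(D).merges[:, 2])
            ref = np.sort(linkage(squareform(D.values), method="average")[:, 2])
            assert np.allclose(mine, ref, atol=1e-10)

    def test_heights_monotone_and_tie_break_deterministic(self):
        D = _dm(np.ones((4, 4)) - np.eye(4))
        tree = ds.upgma(D)
        h = tree.merges[:, 2]
        assert (np.diff(h) >= -1e-12).all()
        # equal distances: label-sorted pair (A, B) merges first
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            _dm([[0, np.nan], [np.nan, 0]])


def _cophenetic(tree):
    members = {i: [lab] for i, lab in enumerate(tree.leaf_labels)}
    n = tree.n_leaves
    out = {}
    for k, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        for la in members[a]:
            for lb in members[b]:
                out[tuple(sorted((la, lb)))] = h
        members[n + k] = members[a] + members[b]
    return out


class TestPermanovaOneway:
    def test_equals_classical_anova_under_squared_euclidean(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            y = rng.normal(size=18)
            g = np.repeat(["a", "b", "c"], 6)
            D = _dm(np.abs(y[:, None] - y[None, :]), ids=[str(i) for i in range(18)])
            res = ds.permanova_oneway(D, g, n_perm=30, seed=1)
            f_ref = sps.f_oneway(y[:6], y[6:12], y[12:]).statistic
            assert res.table.loc[0, "pseudo_F"] == pytest.approx(f_ref, abs=1e-8)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM, permanova

        rng = np.random.default_rng(32)
        X = rng.gamma(1, 1, (12, 5))
        g = np.repeat(["u", "v"], 6)
        D = ds.bray_curtis(X)
        res = ds.permanova_oneway(D, g, n_perm=99, seed=0)
        ref = permanova(SkDM(D.values, ids=D.ids), grouping=list(g), permutations=99)
        assert res.table.loc[0, "pseudo_F"] == pytest.approx(
            ref["test statistic"], abs=1e-8
        )

    def test_ss_additivity(self):
        rng = np.random.default_rng(33)
        X = rng.gamma(1, 1, (10, 4))
        D = ds.bray_curtis(X)
        g = np.repeat(["a", "b"], 5)
        ss_total, ss_within, ss_between = _oneway_ss(D.values**2, g)
        assert ss_between + ss_within == pytest.approx(ss_total, rel=1e-9)

    def test_exact_enumeration_on_small_design(self):
        rng = np.random.default_rng(34)
        X = rng.gamma(1, 1, (6, 3))
        D = ds.bray_curtis(X)
        g = np.repeat(["a", "b"], 3)
        res = ds.permanova_oneway(D, g, n_perm=9999, seed=0)
        assert res.scheme == "exact enumeration"
        assert res.n_permutations == 20
        assert res.table.loc[0, "p"] >= 1 / 20

    def test_degenerate_identical_samples_flagged(self):
        X = np.ones((6, 3))
        D = ds.bray_curtis(X)
        res = ds.permanova_oneway(D, np.repeat(["a", "b"], 3), n_perm=9)
        assert res.degenerate

    def test_singleton_group_rejected_by_name(self):
        D = _dm(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValidationError, match="lonely"):
            ds.permanova_oneway(D, ["lonely", "g", "g"], n_perm=9)

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(35)
        X = rng.gamma(1, 1, (14, 5))
        D = ds.bray_curtis(X)
        g = np.repeat(["a", "b"], 7)
        r1 = ds.permanova_oneway(D, g, n_perm=199, seed=7)
        r2 = ds.permanova_oneway(D, g, n_perm=199, seed=7)
        assert r1.to_json() == r2.to_json()


class TestPermanovaTwoway:
    @staticmethod
    def _balanced(rng, reps=3):
        a = np.repeat(["a1", "a2"], 2 * reps)
        b = np.tile(np.repeat(["b1", "b2"], reps), 2)
        y = rng.normal(size=len(a))
        return y, a, b

    def test_equals_classical_twoway_anova_on_balanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(41)
        for _ in range(5):
            y, a, b = self._balanced(rng)
            D = _dm(np.abs(y[:, None] - y[None, :]), ids=[str(i) for i in range(len(y))])
            res = ds.permanova_twoway(D, a, b, n_perm=20, seed=1)
            df = pd.DataFrame({"y": y, "A": a, "B": b})
            ols = smf.ols("y ~ C(A) + C(B)", data=df).fit()
            ref = sm.stats.anova_lm(ols, typ=1)
            assert res.table.loc[0, "pseudo_F"] == pytest.approx(
                ref.loc["C(A)", "F"], abs=1e-8
            )
            assert res.table.loc[1, "pseudo_F"] == pytest.approx(
                ref.loc["C(B)", "F"], abs=1e-8
            )

    def test_ss_additivity(self):
        rng = np.random.default_rng(42)
        X = rng.gamma(1, 1, (16, 5))
        D = ds.bray_curtis(X)
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        res = ds.permanova_twoway(D, a, b, n_perm=20, seed=0)
        t = res.table.set_index("Source")
        assert t.loc["A", "SS"] + t.loc["B", "SS"] + t.loc["Residual", "SS"] == (
            pytest.approx(t.loc["Total", "SS"], rel=1e-9)
        )

    def test_constant_second_factor_degenerates_to_oneway(self):
        rng = np.random.default_rng(43)
        X = rng.gamma(1, 1, (10, 4))
        D = ds.bray_curtis(X)
        a = np.repeat(["a1", "a2"], 5)
        two = ds.permanova_twoway(D, a, np.repeat("only", 10), n_perm=99, seed=3)
        one = ds.permanova_oneway(D, a, n_perm=99, seed=3)
        assert two.table.loc[0, "pseudo_F"] == pytest.approx(
            one.table.loc[0, "pseudo_F"], abs=1e-12
        )
        assert two.table.loc[0, "p"] == one.table.loc[0, "p"]

    def test_empty_cell_warns(self):
        rng = np.random.default_rng(44)
        X = rng.gamma(1, 1, (9, 4))
        D = ds.bray_curtis(X)
        a = np.repeat(["a1", "a2", "a3"], 3)
        b = np.array(["b1"] * 3 + ["b1", "b2", "b2"] + ["b2"] * 3)
        with pytest.warns(UserWarning, match="empty cells"):
            ds.permanova_twoway(D, a, b, n_perm=9, seed=0)


class TestPermanovaPairwise:
    def test_two_groups_single_row_matches_oneway(self):
        rng = np.random.default_rng(51)
        X = rng.gamma(1, 1, (10, 4))
        D = ds.bray_curtis(X)
        g = np.repeat(["a", "b"], 5)
        pw = ds.permanova_pairwise(D, g, n_perm=99, seed=5)
        one = ds.permanova_oneway(D, g, n_perm=99, seed=5)
        assert len(pw) == 1
        assert pw.loc[0, "pseudo_F"] == pytest.approx(one.table.loc[0, "pseudo_F"])
        assert pw.loc[0, "p"] == one.table.loc[0, "p"]

    def test_pair_count_and_bonferroni_cap(self):
        rng = np.random.default_rng(52)
        X = rng.gamma(1, 1, (12, 4))
        D = ds.bray_curtis(X)
        g = np.repeat(["a", "b", "c", "d"], 3)
        raw = ds.permanova_pairwise(D, g, n_perm=19, seed=0)
        adj = ds.permanova_pairwise(D, g, n_perm=19, seed=0, adjust="bonferroni")
        assert len(raw) == 6
        assert (adj["p"] <= 1.0).all()
        assert np.allclose(adj["p"], np.minimum(1.0, raw["p"] * 6))


class TestKruskalWallis:
    def test_hand_example(self):
        h, p = ds.kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert h == pytest.approx(2.4)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(61)
        for _ in range(10):
            v = rng.integers(0, 5, 20).astype(float)  # heavy ties
            g = rng.choice(["a", "b", "c"], 20)
            if len(set(g)) < 2 or len(set(v)) < 2:
                continue
            h, p = ds.kruskal_wallis(v, g)
            ref = sps.kruskal(*[v[g == lab] for lab in np.unique(g)])
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_values_give_zero(self):
        h, p = ds.kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert h == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(62)
        v = rng.normal(size=15)
        g = np.repeat(["a", "b", "c"], 5)
        h1, _ = ds.kruskal_wallis(v, g)
        h2, _ = ds.kruskal_wallis(np.exp(v), g)
        assert h1 == pytest.approx(h2, abs=1e-12)


class TestDunn:
    def test_two_group_z_squared_close_to_h(self):
        rng = np.random.default_rng(71)
        v = rng.normal(size=14)
        g = np.repeat(["a", "b"], 7)
        h, _ = ds.kruskal_wallis(v, g)
        z = ds.dunns_posthoc(v, g).loc[0, "z"]
        assert z**2 == pytest.approx(h, rel=1e-10)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(72)
        v = rng.normal(size=12)
        g = np.repeat(["a", "b"], 6)
        g_swapped = np.where(g == "a", "b", "a")
        z1 = ds.dunns_posthoc(v, g).loc[0, "z"]
        z2 = ds.dunns_posthoc(v, g_swapped).loc[0, "z"]
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_equal_rank_groups_give_zero(self):
        tab = ds.dunns_posthoc([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert tab.loc[0, "z"] == pytest.approx(0.0)


class TestPooling:
    def test_pool_by_area_sums_weights(self, diet_matrix):
        pooled = ds.pool_matrix(diet_matrix, "area")
        assert pooled.to_numpy().sum() == pytest.approx(
            diet_matrix.weight.to_numpy().sum(), rel=1e-12
        )

    def test_unknown_label_rejected(self, diet_matrix):
        with pytest.raises(ValidationError):
            ds.pool_matrix(diet_matrix, "nonsense")
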