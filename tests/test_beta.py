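import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from planktonic.beta import anosim, bray_curtis, pcoa, simper, upgma
from planktonic.io import CommunityTable, ValidationError
from tests.conftest import random_table


def bc_brute(x, y):
    return 1 - 2 * np.minimum(x, y).sum() / (x + y).sum()


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        t = CommunityTable(pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 5]],
            index=["a", "b", "c"], columns=["x", "y", "z"]))
        dm = bray_curtis(t, normalize=False)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0
        t2 = CommunityTable(pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["a", "b"], columns=["x", "y", "z"]))
        assert bray_curtis(t2, normalize=False)["a", "b"] == pytest.approx(0.5)

    def test_scale_invariance_after_normalization(self):
        base = pd.DataFrame([[3, 5, 2], [1, 7, 2]], index=["a", "b"],
                            columns=["x", "y", "z"])
        scaled = base.copy()
        scaled.loc["a"] *= 13
        d1 = bray_curtis(CommunityTable(base))["a", "b"]
        d2 = bray_curtis(CommunityTable(scaled))["a", "b"]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        t = random_table(rng, 5, 9)
        dm = bray_curtis(t)
        rel = t.relative_abundance().to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert dm.data[i, j] == pytest.approx(
                    bc_brute(rel[i], rel[j]), abs=1e-12)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, list("abc")))
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(7, 3))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(7)])
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, dm.data, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, list("abc")))
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-10)

    def test_matches_skbio_eigenvalues(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(8)
        x = rng.random((6, 4))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(6)])
        mine = pcoa(dm).eigenvalues
        theirs = np.sort(skbio_pcoa(dm).eigvals.to_numpy())[::-1]
        np.testing.assert_allclose(mine[:4], theirs[:4], atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pcoa(DistanceMatrix(np.array([[0., 1], [1, 0]]), list("ab")))


class TestUpgma:
    def test_hand_agglomeration(self):
        d = np.array([[0, .2, .8], [.2, 0, .8], [.8, .8, 0]])
        res = upgma(DistanceMatrix(d, list("ABC")))
        assert res.merges.loc[0, ["cluster_a", "cluster_b"]].tolist() == ["A", "B"]
        assert res.merges.loc[0, "height"] == pytest.approx(0.2)
        assert res.merges.loc[1, "height"] == pytest.approx(0.8)
        assert res.cophenetic()["A", "C"] == pytest.approx(0.8)

    def test_equal_distances_merge_lexicographically(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0)
        res = upgma(DistanceMatrix(d, ["b", "c", "a"]))
        assert res.merges.loc[0, ["cluster_a", "cluster_b"]].tolist() == ["a", "b"]
        assert (res.merges["height"] == 0.5).all()

    def test_ultrametric_and_monotone_heights(self):
        rng = np.random.default_rng(4)
        x = rng.random((8, 5))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(8)])
        res = upgma(dm)
        assert res.merges["height"].is_monotonic_increasing
        c = res.cophenetic().data
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    if len({i, j, k}) == 3:
                        assert c[i, k] <= max(c[i, j], c[j, k]) + 1e-12

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(9)
        x = rng.random((9, 4))
        cond = pdist(x)
        dm = DistanceMatrix(squareform(cond), [f"s{i}" for i in range(9)])
        mine = np.sort(upgma(dm).merges["height"].to_numpy())
        theirs = np.sort(linkage(cond, method="average")[:, 2])
        np.testing.assert_allclose(mine, theirs, atol=1e-10)


def anosim_r_brute(dm, labels):
    """Direct evaluation of the rank formula."""
    from scipy.stats import rankdata
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    within = np.array([labels[i] == labels[j] for i, j in zip(*iu)])
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self, grouped_table):
        table, groups = grouped_table
        res = anosim(bray_curtis(table), groups, n_perm=99, seed=0)
        assert res[0].comparison == "global"
        assert res[0].r_statistic == pytest.approx(1.0)
        assert res[0].p_value >= 1 / 100  # never exactly zero

    def test_matches_brute_force_and_skbio(self):
        rng = np.random.default_rng(12)
        t = random_table(rng, 8, 10)
        labels = {f"s{i}": ("g1" if i % 2 else "g2") for i in range(8)}
        dm = bray_curtis(t)
        mine = anosim(dm, labels, n_perm=49, seed=1, pairwise=False)[0]
        lab = np.array([labels[i] for i in dm.ids])
        assert mine.r_statistic == pytest.approx(
            anosim_r_brute(dm, lab), abs=1e-12)
        sk = skbio_anosim(dm, lab, permutations=0)
        assert mine.r_statistic == pytest.approx(sk["test statistic"],
                                                 abs=1e-10)

    def test_pairwise_results_cover_group_pairs(self, grouped_table):
        table, groups = grouped_table
        groups = dict(groups)
        groups["s2"] = "z"
        groups["s5"] = "z"
        res = anosim(bray_curtis(table), groups, n_perm=19, seed=2)
        assert [r.comparison for r in res] == [
            "global", "x vs y", "x vs z", "y vs z"]

    def test_singleton_group_named_in_error(self, grouped_table):
        table, groups = grouped_table
        groups = dict(groups)
        groups["s0"] = "lonely"
        with pytest.raises(ValidationError, match="lonely"):
            anosim(bray_curtis(table), groups, n_perm=19, seed=0)


class TestSimper:
    def test_two_singleton_groups_decompose_bray_curtis(self):
        t = CommunityTable(pd.DataFrame(
            [[5, 3, 2], [1, 7, 2]], index=["a", "b"], columns=["x", "y", "z"]))
        res = simper(t, {"a": "g1", "b": "g2"})[0]
        dm = bray_curtis(t)
        assert res.mean_dissimilarity == pytest.approx(dm["a", "b"],
                                                       abs=1e-12)
        assert res.contributions["contribution"].sum() == pytest.approx(
            dm["a", "b"], abs=1e-10)

    def test_single_discriminating_otu_contributes_everything(self):
        t = CommunityTable(pd.DataFrame(
            [[5, 5, 0], [5, 5, 0], [5, 0, 5], [5, 0, 5]],
            index=list("abcd"), columns=["x", "y", "z"]))
        res = simper(t, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})[0]
        top2 = res.contributions.iloc[:2]
        assert top2["pct"].sum() == pytest.approx(100.0)
        assert set(top2.index) == {"y", "z"}

    def test_contributions_match_exhaustive_pair_average(self):
        rng = np.random.default_rng(20)
        t = random_table(rng, 4, 3)
        groups = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        res = simper(t, groups)[0]
        rel = t.relative_abundance().to_numpy()
        acc = np.zeros(3)
        for j in (0, 1):
            for k in (2, 3):
                acc += np.abs(rel[j] - rel[k]) / (rel[j] + rel[k]).sum()
        expected = pd.Series(acc / 4, index=t.otu_ids)
        for otu in t.otu_ids:
            assert res.contributions.loc[otu, "contribution"] == pytest.approx(
                expected[otu], abs=1e-12)

    def test_conservation_on_random_fixture(self):
        rng = np.random.default_rng(21)
        t = random_table(rng, 6, 12)
        groups = {f"s{i}": f"g{i % 3}" for i in range(6)}
        results = simper(t, groups)
        rel = t.relative_abundance().to_numpy()
        labels = np.array([groups[s] for s in t.sample_ids])
        for res in results:
            if res.comparison == "pooled":
                continue
            ga, gb = res.comparison.split(" vs ")
            dms = []
            for j in np.flatnonzero(labels == ga):
                for k in np.flatnonzero(labels == gb):
                    dms.append(bc_brute(rel[j], rel[k]))
            assert res.contributions["contribution"].sum() == pytest.approx(
                np.mean(dms), abs=1e-10)
            assert (res.contributions["contribution"] >= 0).all()
            assert res.contributions["cumulative_pct"].is_monotonic_increasing

    def test_selected_prefix_reaches_cut(self):
        rng = np.random.default_rng(22)
        t = random_table(rng, 4, 10)
        res = simper(t, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"},
                     cumulative_cut=0.5)[0]
        cum = res.contributions["cumulative_pct"]
        assert cum[res.selected[-1]] >= 50.0 - 1e-9
        if len(res.selected) > 1:
            assert cum[res.selected[-2]] < 50.0
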