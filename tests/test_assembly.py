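import io as stdio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from planktonic.assembly import (assembly_analysis, beta_mntd,
                                 beta_mntd_matrix, bnti, classify_processes,
                                 cophenetic_matrix, rc_bray, rc_scale,
                                 summarize_processes)
from planktonic.io import CommunityTable, ValidationError, read_newick
from planktonic.simulate import simulate_tree
from tests.conftest import random_table


def _table(rows, otus):
    rows = np.atleast_2d(rows)
    return CommunityTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=otus))


def bmntd_brute(fj, fk, d):
    """Literal double-loop over taxa present in each sample."""
    sj = [i for i, v in enumerate(fj) if v > 0]
    sk = [i for i, v in enumerate(fk) if v > 0]
    left = sum(fj[i] * min(d[i, t] for t in sk) for i in sj)
    right = sum(fk[i] * min(d[i, t] for t in sj) for i in sk)
    return 0.5 * (left + right)


class TestCophenetic:
    def test_hand_path_sums(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        d = cophenetic_matrix(tree)
        assert d["A", "B"] == 2 and d["A", "C"] == 4 and d["B", "C"] == 4

    def test_star_tree_all_equal(self):
        tree = read_newick("(A:3,B:3,C:3,D:3);")
        d = cophenetic_matrix(tree).data
        off = d[np.triu_indices(4, 1)]
        assert np.allclose(off, 6.0)

    def test_matches_independent_tree_library(self):
        tree = simulate_tree(8, seed=17)
        newick = tree.as_string(schema="newick").replace("[&R] ", "")
        d = cophenetic_matrix(tree)
        sk = TreeNode.read(stdio.StringIO(newick))
        theirs = sk.tip_tip_distances(list(d.ids))
        np.testing.assert_allclose(d.data, theirs.data, atol=1e-10)

    def test_missing_tips_listed(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValidationError, match="X.*Y|\\['X', 'Y'\\]"):
            cophenetic_matrix(tree, ["A", "X", "Y"])


class TestBetaMntd:
    def setup_method(self):
        self.tree = read_newick("((A:1,B:1):1,C:2);")
        self.d = cophenetic_matrix(self.tree).data

    def test_identical_communities_zero(self):
        f = np.array([0.5, 0.3, 0.2])
        assert beta_mntd(f, f, self.d) == 0.0

    def test_single_taxon_pair_is_patristic_distance(self):
        fa = np.array([1.0, 0, 0])
        fc = np.array([0, 0, 1.0])
        assert beta_mntd(fa, fc, self.d) == pytest.approx(4.0)

    def test_matches_brute_force_with_unequal_weights(self):
        tree = simulate_tree(4, seed=3)
        d = cophenetic_matrix(tree).data
        rng = np.random.default_rng(0)
        for _ in range(20):
            fj = rng.dirichlet(np.ones(4)) * (rng.random(4) > 0.3)
            fk = rng.dirichlet(np.ones(4)) * (rng.random(4) > 0.3)
            if fj.sum() == 0 or fk.sum() == 0:
                continue
            fj, fk = fj / fj.sum(), fk / fk.sum()
            assert beta_mntd(fj, fk, d) == pytest.approx(
                bmntd_brute(fj, fk, d), abs=1e-12)

    def test_matrix_form_equals_pairwise_calls(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 5, 7)
        rel = t.relative_abundance().to_numpy()
        tree = simulate_tree(7, seed=9)
        d = cophenetic_matrix(tree).data
        b = beta_mntd_matrix(rel, d)
        for i in range(5):
            for j in range(5):
                assert b[i, j] == pytest.approx(
                    beta_mntd(rel[i], rel[j], d), abs=1e-12)
        assert np.allclose(b, b.T) and np.allclose(np.diag(b), 0)


class TestBnti:
    def test_reproducible_bit_identical(self):
        rng = np.random.default_rng(31)
        t = random_table(rng, 4, 6)
        t = CommunityTable(t.counts.set_axis(
            [f"OTU{i + 1:04d}" for i in range(6)], axis=1))
        tree = simulate_tree(6, seed=2)
        coph = cophenetic_matrix(tree, t.otu_ids)
        a = bnti(t, coph, n_null=29, seed=8)
        b = bnti(t, coph, n_null=29, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_pair_degenerate_and_near_identical_nonpositive(self):
        # identical supports: betaMNTD is 0 under every label permutation
        # too, so the null has zero spread and betaNTI is undefined
        counts = [[4, 3, 2, 1, 0, 0], [4, 3, 2, 1, 0, 0], [0, 0, 1, 2, 3, 4]]
        tree = simulate_tree(6, seed=4)
        t = _table(counts, [f"OTU{i + 1:04d}" for i in range(6)])
        coph = cophenetic_matrix(tree, t.otu_ids)
        res = bnti(t, coph, n_null=49, seed=1)
        row = res[(res.sample_j == "s0") & (res.sample_k == "s1")].iloc[0]
        assert row.bmntd_obs == 0.0 and np.isnan(row.bnti)
        # nearly identical supports: observed sits at the low extreme of
        # the null, so the z-score is negative
        counts2 = [[40, 30, 20, 1, 0, 0], [40, 30, 20, 0, 1, 0],
                   [0, 0, 1, 2, 3, 4]]
        t2 = _table(counts2, [f"OTU{i + 1:04d}" for i in range(6)])
        res2 = bnti(t2, coph, n_null=199, seed=1)
        row2 = res2[(res2.sample_j == "s0") & (res2.sample_k == "s1")].iloc[0]
        assert row2.bnti <= 0

    def test_star_tree_degenerate_flagged_not_crashing(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        t = _table([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
                   ["A", "B", "C", "D"])
        coph = cophenetic_matrix(tree, t.otu_ids)
        res = bnti(t, coph, n_null=19, seed=0)
        assert res["bnti"].isna().all()
        labels, flagged = classify_processes(res["bnti"].to_numpy(),
                                             np.zeros(len(res)))
        assert flagged.all() and (labels == "drift").all()

    def test_label_permutation_equals_tip_shuffle(self):
        """The cophenetic-label null must agree with physically relabeling
        the tree's tips by the same permutations."""
        import dendropy
        tree = simulate_tree(7, seed=12)
        rng0 = np.random.default_rng(33)
        t = random_table(rng0, 4, 7, max_count=3)  # sparse: partial supports
        t = CommunityTable(t.counts.set_axis(
            sorted(l.label for l in tree.taxon_namespace), axis=1))
        coph = cophenetic_matrix(tree, t.otu_ids)
        res = bnti(t, coph, n_null=13, seed=77)

        # independent route: shuffle tip names on a copy of the tree itself
        rel = t.relative_abundance()[list(coph.ids)].to_numpy()
        rng = np.random.default_rng(77)
        nulls = []
        for _ in range(13):
            perm = rng.permutation(len(coph.ids))
            inv = np.argsort(perm)  # tip at old position p becomes ids[inv[p]]
            shuffled = dendropy.Tree(tree)
            ids = list(coph.ids)
            for leaf in shuffled.leaf_node_iter():
                pos = ids.index(leaf.taxon.label)
                leaf.taxon = dendropy.Taxon(f"relabel_{ids[inv[pos]]}")
            # rebuild the namespace after relabeling
            shuffled.update_taxon_namespace()
            d2 = cophenetic_matrix(shuffled,
                                   [f"relabel_{o}" for o in ids]).data
            nulls.append(beta_mntd_matrix(rel, d2))
        nulls = np.stack(nulls)
        iu = np.triu_indices(4, 1)
        mean = nulls.mean(axis=0)[iu]
        sd = nulls.std(axis=0, ddof=1)[iu]
        obs = beta_mntd_matrix(rel, coph.data)[iu]
        np.testing.assert_allclose(res["null_mean"], mean, atol=1e-10)
        np.testing.assert_allclose(res["null_sd"], sd, atol=1e-10)
        with np.errstate(invalid="ignore"):
            expected_z = (obs - mean) / sd  # NaN where the null is degenerate
        np.testing.assert_allclose(res["bnti"], expected_z, atol=1e-10)


class TestRcBray:
    def test_rescaling_endpoints_and_ties(self):
        assert rc_scale(99, 0, 99) == 1.0
        assert rc_scale(0, 0, 99) == -1.0
        assert rc_scale(0, 99, 99) == 0.0

    def test_identical_rich_pair_near_minus_one(self):
        rng = np.random.default_rng(40)
        base = rng.integers(1, 20, size=12)
        other = rng.integers(0, 20, size=12)
        other[0] += 1
        t = _table([base, base, other], [f"o{i}" for i in range(12)])
        res = rc_bray(t, n_null=99, seed=3)
        row = res[(res.sample_j == "s0") & (res.sample_k == "s1")].iloc[0]
        assert row.rc_bray < -0.9

    def test_disjoint_pair_positive_extreme(self):
        # two samples with disjoint supports, rich relative to the pool so
        # null assemblies almost surely overlap (obs BC = 1 beats the null)
        a = np.array([5] * 8 + [0] * 12)
        b = np.array([0] * 8 + [5] * 8 + [0] * 4)
        c = np.ones(20, dtype=int)
        t = _table([a, b, c], [f"o{i}" for i in range(20)])
        res = rc_bray(t, n_null=99, seed=5)
        row = res[(res.sample_j == "s0") & (res.sample_k == "s1")].iloc[0]
        assert row.rc_bray > 0.95


class TestClassification:
    @pytest.mark.parametrize("b,r,expected", [
        (2.5, 0.0, "heterogeneous_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (0.5, 0.97, "dispersal_limitation"),
        (0.5, -0.97, "homogenizing_dispersal"),
        (0.5, 0.2, "drift"),
        (2.0, 0.2, "drift"),  # boundary is strict
    ])
    def test_rule_table(self, b, r, expected):
        labels, flagged = classify_processes(np.array([b]), np.array([r]))
        assert labels[0] == expected and not flagged[0]

    def test_undefined_bnti_classified_by_rc_and_flagged(self):
        labels, flagged = classify_processes(
            np.array([np.nan]), np.array([0.97]))
        assert labels[0] == "dispersal_limitation" and flagged[0]

    def test_rc_cut_only_moves_mass_between_dispersal_and_drift(self):
        rng = np.random.default_rng(50)
        b = rng.normal(0, 2, 200)
        r = rng.uniform(-1, 1, 200)
        l1, _ = classify_processes(b, r, rc_cut=0.5)
        l2, _ = classify_processes(b, r, rc_cut=0.95)
        sel = {"heterogeneous_selection", "homogeneous_selection"}
        assert np.array_equal(np.isin(l1, list(sel)), np.isin(l2, list(sel)))
        disp1 = np.isin(l1, ["dispersal_limitation", "homogenizing_dispersal"])
        disp2 = np.isin(l2, ["dispersal_limitation", "homogenizing_dispersal"])
        assert disp2.sum() <= disp1.sum()  # tighter cut -> more drift


class TestSummary:
    def test_all_drift(self):
        df = pd.DataFrame({"process": ["drift"] * 5})
        s = summarize_processes(df)
        assert s.percent["drift"] == 100.0

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"process": rng.choice(
            ["drift", "dispersal_limitation", "homogeneous_selection"], 351)})
        s = summarize_processes(df)
        assert sum(s.percent.values()) == pytest.approx(100, abs=1e-9)
        assert s.n_pairs == 351  # 27 samples -> 27*26/2 pairs

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_processes(pd.DataFrame({"process": []}))


def test_full_analysis_smoke_and_pair_count():
    rng = np.random.default_rng(60)
    t = random_table(rng, 6, 10)
    t = CommunityTable(t.counts.set_axis(
        [f"OTU{i + 1:04d}" for i in range(10)], axis=1))
    tree = simulate_tree(10, seed=1)
    pairs, summary = assembly_analysis(t, tree, n_null=29, seed=2)
    assert len(pairs) == 15
    assert set(pairs["process"]) <= set(
        ["heterogeneous_selection", "homogeneous_selection",
         "dispersal_limitation", "homogenizing_dispersal", "drift"])
    assert sum(summary.percent.values()) == pytest.approx(100, abs=1e-9)
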