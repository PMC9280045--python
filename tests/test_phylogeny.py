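import math

import numpy as np
import pytest

import nj_oracle
from woxkit import phylogeny as ph
from woxkit import synthetic_data as sim
from woxkit.io_formats import SequenceRecord


def aln(*pairs):
    return ph.Alignment(
        [SequenceRecord(i, s, alphabet="protein-aligned") for i, s in pairs]
    )


def labelled_matrix(d):
    n = d.shape[0]
    return ph.DistanceMatrix([f"t{i}" for i in range(n)], d)


class TestPairwiseDistance:
    def test_p_distance(self):
        dm = ph.pairwise_distance(aln(("a", "AAAA"), ("b", "AATT")))
        assert dm.get("a", "b") == pytest.approx(0.5)

    def test_pairwise_gap_deletion(self):
        dm = ph.pairwise_distance(aln(("a", "A-AA"), ("b", "AGAT")))
        assert dm.get("a", "b") == pytest.approx(1 / 3)

    def test_identical_sequences_zero_under_both_models(self):
        for model in ("p", "poisson"):
            dm = ph.pairwise_distance(aln(("a", "MKV"), ("b", "MKV")), model)
            assert dm.get("a", "b") == 0.0

    def test_poisson_correction(self):
        dm = ph.pairwise_distance(aln(("a", "AAAA"), ("b", "AATT")), "poisson")
        assert dm.get("a", "b") == pytest.approx(-math.log(0.5))

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            ph.pairwise_distance(aln(("a", "A--"), ("b", "-AA"), ("c", "AAA")))

    def test_saturated_pair_rejected_under_poisson(self):
        with pytest.raises(ValueError, match="saturated"):
            ph.pairwise_distance(aln(("a", "AAAA"), ("b", "TTTT")), "poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_point_additive_exact(self):
        # tree ((A:1,B:2),(C:3,D:4)) with internal edge 1
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = ph.DistanceMatrix(["A", "B", "C", "D"], d)
        tree = ph.neighbor_joining(dm)
        assert ph.bipartitions(tree) == {frozenset({"C", "D"})}
        back = ph.tree_distance_matrix(tree)
        np.testing.assert_allclose(
            back.as_dataframe().loc[dm.labels, dm.labels].to_numpy(), d,
            atol=1e-9,
        )

    def test_additive_path_lengths_reproduced(self, rng):
        for n in (5, 6):
            d, _ = nj_oracle.random_additive(n, rng)
            dm = labelled_matrix(d)
            tree = ph.neighbor_joining(dm)
            back = ph.tree_distance_matrix(tree)
            np.testing.assert_allclose(
                back.as_dataframe().loc[dm.labels, dm.labels].to_numpy(), d,
                atol=1e-9,
            )

    def test_taxon_order_invariance(self, rng):
        d, _ = nj_oracle.random_additive(6, rng)
        labels = [f"t{i}" for i in range(6)]
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        perm = rng.permutation(6)
        tree_p = ph.neighbor_joining(
            ph.DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert ph.bipartitions(tree) == ph.bipartitions(tree_p)

    def test_agrees_with_dendropy_nj(self, rng):
        # independent implementation cross-check on a noisy matrix
        import dendropy

        d, _ = nj_oracle.random_additive(7, rng)
        d = d + d * rng.uniform(-0.01, 0.01, size=d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(7)]
        mine = ph.neighbor_joining(ph.DistanceMatrix(labels, d))

        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(str(x) for x in d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        theirs_splits = set()
        all_leaves = frozenset(labels)
        for node in theirs.preorder_node_iter():
            if node is theirs.seed_node or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if min(all_leaves) in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                theirs_splits.add(side)
        assert ph.bipartitions(mine) == theirs_splits

    def test_matches_least_squares_oracle_small(self, rng):
        for n in (4, 5, 6):
            for _ in range(5):
                d, true_splits = nj_oracle.random_additive(n, rng)
                tree = ph.neighbor_joining(labelled_matrix(d))
                got = {
                    frozenset(int(x[1:]) for x in s)
                    for s in ph.bipartitions(tree)
                }
                assert got == set(nj_oracle.least_squares_topology(d))
                assert got == set(true_splits)


class TestBootstrap:
    def test_repeated_column_alignment_gives_full_support(self):
        col = {"a": "A", "b": "A", "c": "C", "d": "C"}
        records = [(k, v * 50) for k, v in col.items()]
        # add one variable column so distances differ between pairs
        records = [(k, v + ("A" if k in "ab" else "T")) for k, v in records]
        tree = ph.bootstrap_support(aln(*records), n_reps=20, seed=1)
        supports = [
            node.support
            for node in tree.preorder_node_iter()
            if hasattr(node, "support")
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_binary(self):
        aln6, _ = sim.simulate_alignment_on_tree(
            "((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2,(E:0.2,F:0.2):0.2);",
            200, 1.0, seed=2,
        )
        tree = ph.bootstrap_support(aln6, n_reps=1, seed=3)
        for node in tree.preorder_node_iter():
            if hasattr(node, "support"):
                assert node.support in (0.0, 100.0)

    def test_seed_determinism(self):
        aln6, _ = sim.simulate_alignment_on_tree(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,E:0.5);", 150, 1.0, seed=4
        )
        t1 = ph.bootstrap_support(aln6, n_reps=25, seed=7)
        t2 = ph.bootstrap_support(aln6, n_reps=25, seed=7)
        s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
        assert s1 == s2


class TestAssignClades:
    @pytest.fixture
    def toy_matrix(self):
        labels = ["anc1", "int1", "mod1", "g1", "g2"]
        d = np.array(
            [
                [0.0, 0.8, 0.9, 0.1, 0.5],
                [0.8, 0.0, 0.7, 0.8, 0.5],
                [0.9, 0.7, 0.0, 0.9, 0.9],
                [0.1, 0.8, 0.9, 0.0, 0.6],
                [0.5, 0.5, 0.9, 0.6, 0.0],
            ]
        )
        return ph.DistanceMatrix(labels, d)

    ANCHORS = {"anc1": "ancient", "int1": "intermediate", "mod1": "modern"}

    def test_nearest_anchor_wins(self, toy_matrix):
        out = ph.assign_clades(toy_matrix, self.ANCHORS)
        assert out.loc["g1", "clade"] == "ancient"
        assert out.loc["g1", "margin"] > 0

    def test_equidistant_gene_ambiguous(self, toy_matrix):
        out = ph.assign_clades(toy_matrix, self.ANCHORS)
        assert out.loc["g2", "clade"] == "ambiguous"
        assert out.loc["g2", "margin"] == 0

    def test_missing_anchor_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="missing"):
            ph.assign_clades(toy_matrix, {"nope": "ancient", "int1": "modern"})

    def test_simulated_family_recovers_clades(self):
        # three clade subtrees around long internal branches, low rate
        newick = (
            "((anc:0.02,a1:0.02,a2:0.02):0.5,"
            "(int:0.02,i1:0.02,i2:0.02):0.5,"
            "(mod:0.02,m1:0.02,m2:0.02):0.5);"
        )
        alignment, _ = sim.simulate_alignment_on_tree(newick, 400, 0.5, seed=6)
        dm = ph.pairwise_distance(alignment)
        anchors = {"anc": "ancient", "int": "intermediate", "mod": "modern"}
        out = ph.assign_clades(dm, anchors)
        expected = {"a1": "ancient", "a2": "ancient", "i1": "intermediate",
                    "i2": "intermediate", "m1": "modern", "m2": "modern"}
        for gene, clade in expected.items():
            assert out.loc[gene, "clade"] == clade


class TestCladeProportions:
    def test_printed_split(self):
        got = ph.clade_proportions({"modern": 38, "intermediate": 12, "ancient": 9})
        assert got == {"modern": 64.4, "intermediate": 20.3, "ancient": 15.3}

    def test_half_away_from_zero(self):
        # 1/8 = 12.5% must round up to 12.5 -> 12.5; 0.125 -> check boundary
        assert ph.clade_proportions({"a": 1, "b": 7}) == {"a": 12.5, "b": 87.5}
        assert ph._round_half_away(0.25, 1) == 0.3
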