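"""NJ trees, bootstrap supports, monophyly, anchor-based clade assignment."""

import dendropy
import numpy as np
import pytest

from clsymine.align import Msa
from clsymine.phylo import (
    DistanceMatrix,
    assign_clades,
    bipartitions,
    bootstrap_support,
    is_monophyletic,
    msa_distances,
    nj_tree,
    read_newick,
    robinson_foulds,
    select_spanning_anchors,
    write_newick,
    write_phylip,
)

from conftest import random_additive_matrix


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestDistances:
    def test_identical_rows_zero(self):
        msa = Msa((("a", "WKDEH"), ("b", "WKDEH")))
        dm = msa_distances(msa, "p")
        assert dm.d[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        a = "W" * 100
        b = "F" * 5 + "W" * 95
        dm = msa_distances(Msa((("a", a), ("b", b))), "p")
        assert dm.d[0, 1] == pytest.approx(0.05)

    def test_poisson_correction_closed_form(self):
        a = "W" * 100
        b = "F" * 5 + "W" * 95
        dm = msa_distances(Msa((("a", a), ("b", b))), "poisson")
        assert dm.d[0, 1] == pytest.approx(-np.log(0.95))

    def test_gap_only_overlap_is_an_error(self):
        msa = Msa((("left", "WK--"), ("right", "--WK")))
        with pytest.raises(ValueError, match="left"):
            msa_distances(msa)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)); additive distances
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        assert {frozenset(p) for p in bipartitions(tree)} == {
            frozenset({"c", "d"})} | set()
        # branch lengths: pendant edges recover the generating values
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.1)

    def test_additive_matrices_recovered_exactly(self):
        """RF distance 0 to the generating topology on random additive
        matrices of up to 12 taxa."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            true_tree, dm = random_additive_matrix(n, rng)
            assert robinson_foulds(true_tree, nj_tree(dm)) == 0

    def test_rf_agrees_with_dendropy(self):
        """The explicit bipartition-set RF equals dendropy's symmetric
        difference (independent implementation cross-check)."""
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(3)
        t1, _ = random_additive_matrix(8, rng)
        t2, _ = random_additive_matrix(8, rng)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        expected = treecompare.symmetric_difference(a, b)
        assert robinson_foulds(t1, t2) == expected

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestBootstrap:
    def test_identical_sequences_supports_bounded(self):
        msa = Msa(tuple((f"s{i}", "WKDEHWKDEH") for i in range(5)))
        tree = bootstrap_support(msa, 20, seed=1)
        for node in tree.preorder_node_iter():
            support = getattr(node, "support", None)
            if support is not None:
                assert 0 <= support <= 100

    def test_subfamily_split_strongly_supported(self, subfamily_msa):
        tree = bootstrap_support(subfamily_msa["msa"], 100, seed=7)
        clade1 = {p for p, _ in subfamily_msa["records"]
                  if p.startswith("clade1")}
        supports = [node.support for node in tree.preorder_node_iter()
                    if not node.is_leaf() and node is not tree.seed_node
                    and getattr(node, "support", None) is not None
                    and {l.taxon.label for l in node.leaf_iter()}
                    in (clade1, {p for p, _ in subfamily_msa["records"]}
                        - clade1)]
        assert supports and min(supports) >= 95

    def test_same_seed_same_supports(self, subfamily_msa):
        def supports(tree):
            return sorted((frozenset(l.taxon.label for l in nd.leaf_iter()),
                           nd.support)
                          for nd in tree.preorder_node_iter()
                          if getattr(nd, "support", None) is not None)

        t1 = bootstrap_support(subfamily_msa["msa"], 25, seed=5)
        t2 = bootstrap_support(subfamily_msa["msa"], 25, seed=5)
        assert supports(t1) == supports(t2)


class TestMonophyly:
    CATERPILLAR = "((((((a:1,b:1):1,c:1):1,d:1):1,e:1):1,f:1):1);"

    def test_all_leaves_and_singletons_trivially_monophyletic(self):
        tree = tree_from_newick(self.CATERPILLAR)
        assert is_monophyletic(tree, {"a", "b", "c", "d", "e", "f"})
        assert is_monophyletic(tree, {"d"})

    def test_opposite_ends_of_caterpillar_not_monophyletic(self):
        tree = tree_from_newick(self.CATERPILLAR)
        assert not is_monophyletic(tree, {"a", "f"})
        assert is_monophyletic(tree, {"a", "b"})
        assert is_monophyletic(tree, {"a", "b", "c"})

    def test_unknown_leaf_rejected(self):
        tree = tree_from_newick(self.CATERPILLAR)
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(tree, {"a", "zz"})


class TestCladeAssignment:
    def test_synthetic_truth_recovered(self, subfamily_msa):
        tree = nj_tree(msa_distances(subfamily_msa["msa"]))
        records = subfamily_msa["records"]
        groups = {
            "clade1": {p for p, _ in records if p.startswith("clade1")},
            "clade2": {p for p, _ in records if p.startswith("clade2")},
        }
        anchors = select_spanning_anchors(tree, groups)
        assignment = assign_clades(tree, anchors)
        for pid, _ in records:
            assert assignment[pid] == pid[:6]

    def test_anchor_keeps_own_label(self, subfamily_msa):
        tree = nj_tree(msa_distances(subfamily_msa["msa"]))
        anchors = {"clade1_000": "one", "clade1_001": "one",
                   "clade2_000": "two", "clade2_001": "two"}
        assignment = assign_clades(tree, anchors)
        assert assignment["clade1_000"] == "one"
        assert assignment["clade2_001"] == "two"

    def test_grafted_background_is_outlier(self, subfamily_msa):
        """A leaf grafted onto the subfamily-split edge sits outside both
        anchor clades and must come out as an outlier."""
        tree = nj_tree(msa_distances(subfamily_msa["msa"]))
        records = subfamily_msa["records"]
        groups = {
            "clade1": {p for p, _ in records if p.startswith("clade1")},
            "clade2": {p for p, _ in records if p.startswith("clade2")},
        }
        anchors = select_spanning_anchors(tree, groups)
        split_node = next(
            nd for nd in tree.preorder_node_iter()
            if {l.taxon.label for l in nd.leaf_iter()} in groups.values())
        parent = split_node.parent_node
        mid = dendropy.Node()
        parent.remove_child(split_node)
        parent.add_child(mid)
        mid.edge.length = split_node.edge.length / 2
        split_node.edge.length /= 2
        mid.add_child(split_node)
        graft = dendropy.Node(
            taxon=tree.taxon_namespace.new_taxon(label="grafted_bg"))
        graft.edge.length = 2.0
        mid.add_child(graft)
        assignment = assign_clades(tree, anchors)
        assert assignment["grafted_bg"] == "outlier"

    def test_interleaved_anchors_are_ambiguous(self):
        tree = tree_from_newick(
            "((((a1:1,b1:1):1,a2:1):1,b2:1):1,(x:1,y:1):1);")
        anchors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        with pytest.raises(ValueError, match="ambiguous"):
            assign_clades(tree, anchors)

    def test_unknown_anchor_rejected(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="anchor"):
            assign_clades(tree, {"zz": "A"})


def test_newick_and_phylip_io(tmp_path, subfamily_msa):
    tree = nj_tree(msa_distances(subfamily_msa["msa"]))
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert {l.taxon.label for l in back.leaf_node_iter()} == \
        {p for p, _ in subfamily_msa["records"]}
    phy = tmp_path / "aln.phy"
    write_phylip(subfamily_msa["msa"], phy)
    header = phy.read_text().splitlines()[0].split()
    assert header == ["12", str(subfamily_msa["msa"].column_count)]
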