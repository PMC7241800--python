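"""NJ tree construction, monophyly flags, threshold clustering, consistency report."""

import numpy as np
import pytest
from skbio import TreeNode

from barcodeqc.distance import DistanceMatrix
from barcodeqc.treecheck import (
    consistency_report,
    monophyly_flags,
    nj_tree,
    threshold_clusters,
)
from conftest import matrix_from_dict


def dm_from_array(ids, values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(list(ids), values, np.zeros_like(values, dtype=int))


def random_additive_case(n_taxa, seed):
    """A random unrooted binary tree and its exact tip-tip distance matrix."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.02, 0.10))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.02, 0.10))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = TreeNode(children=nodes)
    ids = [f"t{i}" for i in range(n_taxa)]
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            d[a, b] = d[b, a] = tree.find(ids[a]).distance(tree.find(ids[b]))
    return tree, dm_from_array(ids, d)


def bipartitions(tree):
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips(include_self=True))
        if 1 < len(side) < len(tips) - 1:
            out.add(frozenset((side, tips - side)))
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        # d_ab=0.06, d_ac=0.08, d_bc=0.10 -> la=(d_ab+d_ac-d_bc)/2=0.02,
        # lb=0.04, lc=0.06
        dm = dm_from_array(["a", "b", "c"],
                           [[0, 0.06, 0.08], [0.06, 0, 0.10], [0.08, 0.10, 0]])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.02)
        assert lengths["b"] == pytest.approx(0.04)
        assert lengths["c"] == pytest.approx(0.06)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # ((a:0.02, b:0.03):0.01, c:0.02, d:0.04) as an unrooted quartet
        ids = ["a", "b", "c", "d"]
        d = [
            [0, 0.05, 0.05, 0.07],
            [0.05, 0, 0.06, 0.08],
            [0.05, 0.06, 0, 0.06],
            [0.07, 0.08, 0.06, 0],
        ]
        dm = dm_from_array(ids, d)
        tree = nj_tree(dm)
        assert frozenset([frozenset("ab"), frozenset("cd")]) in bipartitions(tree)
        for i, a in enumerate(ids):
            for j in range(i + 1, 4):
                got = tree.find(a).distance(tree.find(ids[j]))
                assert got == pytest.approx(d[i][j], abs=1e-12)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_additive_trees_recovered(self, n_taxa, seed):
        source, dm = random_additive_case(n_taxa, seed)
        tree = nj_tree(dm)
        assert bipartitions(tree) == bipartitions(source)
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                got = tree.find(a).distance(tree.find(dm.ids[j]))
                assert got == pytest.approx(dm.values[i, j], abs=1e-10)

    def test_equidistant_matrix_tie_break_deterministic(self):
        n = 5
        d = np.full((n, n), 0.1)
        np.fill_diagonal(d, 0.0)
        ids = [f"r{i}" for i in range(n)]
        t1 = str(nj_tree(dm_from_array(ids, d)))
        t2 = str(nj_tree(dm_from_array(ids, d)))
        assert t1 == t2

    def test_fewer_than_three_records_rejected(self):
        dm = dm_from_array(["a", "b"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_missing_distances_imputed(self):
        ids = ["a", "b", "c", "d"]
        dm = matrix_from_dict(
            ids,
            {("a", "b"): 0.01, ("a", "c"): 0.1, ("b", "c"): 0.1,
             ("a", "d"): 0.1, ("b", "d"): 0.1},  # (c, d) missing
        )
        tree = nj_tree(dm)  # must not raise
        assert {t.name for t in tree.tips()} == set(ids)


class TestMonophyly:
    def test_clean_split_both_monophyletic(self):
        tree = TreeNode.read(["((a1:0.01,a2:0.01):0.05,(b1:0.01,b2:0.01):0.05);"])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        tci = monophyly_flags(tree, labels)
        assert tci["A"] == 0 and tci["B"] == 0

    def test_interleaved_tips_both_flagged(self):
        tree = TreeNode.read(["((a1:0.01,b1:0.01):0.05,(a2:0.01,b2:0.01):0.05);"])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        tci = monophyly_flags(tree, labels)
        assert tci["A"] == 2 and tci["B"] == 2

    def test_nested_mislabel_flags_both_species(self):
        tree = TreeNode.read(
            ["(((a1:0.01,x1:0.01):0.01,a2:0.01):0.05,(b1:0.01,b2:0.01):0.05);"]
        )
        labels = {"a1": "A", "a2": "A", "x1": "B", "b1": "B", "b2": "B"}
        tci = monophyly_flags(tree, labels)
        assert tci["A"] == 2  # A's tips no longer form a bipartition
        assert tci["B"] == 3

    def test_monotypic_species_trivially_monophyletic(self):
        tree = TreeNode.read(["((a1:0.01,a2:0.01):0.05,c1:0.06);"])
        tci = monophyly_flags(tree, {"a1": "A", "a2": "A", "c1": "C"})
        assert tci["C"] == 0


class TestClusters:
    def test_two_separated_species_two_homogeneous_clusters(self):
        ids = ["a1", "a2", "b1", "b2"]
        dist = {("a1", "a2"): 0.01, ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.1, ("a1", "b2"): 0.1,
                ("a2", "b1"): 0.1, ("a2", "b2"): 0.1}
        clusters = threshold_clusters(matrix_from_dict(ids, dist), 0.054)
        assert clusters["a1"] == clusters["a2"]
        assert clusters["b1"] == clusters["b2"]
        assert clusters["a1"] != clusters["b1"]

    def test_single_linkage_chains_transitively(self):
        ids = ["a", "b", "c"]
        dist = {("a", "b"): 0.04, ("b", "c"): 0.04, ("a", "c"): 0.09}
        clusters = threshold_clusters(matrix_from_dict(ids, dist), 0.054)
        assert len(set(clusters)) == 1

    def test_complete_linkage_respects_chain_break(self):
        ids = ["a", "b", "c"]
        dist = {("a", "b"): 0.04, ("b", "c"): 0.04, ("a", "c"): 0.09}
        clusters = threshold_clusters(
            matrix_from_dict(ids, dist), 0.054, linkage_method="complete"
        )
        assert len(set(clusters)) == 2

    def test_partition_property(self, clean_matrix):
        clusters = threshold_clusters(clean_matrix, 0.054)
        assert set(clusters.index) == set(clean_matrix.ids)
        assert clusters.notna().all()


class TestConsistencyReport:
    def _setup(self, dist, labels, threshold=0.054):
        ids = list(labels)
        dm = matrix_from_dict(ids, dist, default=0.2)
        tree = nj_tree(dm)
        clusters = threshold_clusters(dm, threshold)
        return consistency_report(tree, clusters, labels)

    def test_clean_library_all_flags_zero(self, clean_matrix, clean_library):
        lib, _ = clean_library
        tree = nj_tree(clean_matrix)
        clusters = threshold_clusters(clean_matrix, 0.054)
        report = consistency_report(tree, clusters, lib.labels)
        assert (report.per_species[["tci", "cl_het", "sp_split", "other_homog"]]
                .to_numpy().sum() == 0)
        assert report.n_heterospecific_clusters == 0
        # clusters coincide with species
        assert report.clusters.nunique() == lib.species_counts().size

    def test_geographic_split_yields_other_homog(self):
        # species A falls into two tight, widely separated homogeneous
        # clusters but remains monophyletic
        labels = {"a1": "A", "a2": "A", "a3": "A", "a4": "A", "b1": "B", "b2": "B"}
        dist = {
            ("a1", "a2"): 0.01, ("a3", "a4"): 0.01,
            ("a1", "a3"): 0.08, ("a1", "a4"): 0.08,
            ("a2", "a3"): 0.08, ("a2", "a4"): 0.08,
            ("b1", "b2"): 0.01,
        }
        report = self._setup(dist, labels)
        row = report.per_species.set_index("species").loc["A"]
        assert row["other_homog"] == 4
        assert row["sp_split"] == 0
        assert row["tci"] == 0

    def test_mislabel_contaminates_cluster_as_heterogeneous(self):
        # x1 labeled B but sits inside A's cloud
        labels = {"a1": "A", "a2": "A", "x1": "B", "b1": "B", "b2": "B"}
        dist = {
            ("a1", "a2"): 0.01, ("a1", "x1"): 0.01, ("a2", "x1"): 0.01,
            ("b1", "b2"): 0.01,
        }
        report = self._setup(dist, labels)
        per = report.per_species.set_index("species")
        assert per.loc["A", "cl_het"] == 2  # both A records share a cluster with x1
        assert per.loc["B", "cl_het"] == 1  # x1 itself
        assert per.loc["B", "sp_split"] == 3  # B spread over 2 clusters, one mixed
        assert report.n_heterospecific_clusters == 1

    def test_record_set_mismatch_rejected(self):
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        dm = matrix_from_dict(list(labels), {("a1", "a2"): 0.01}, default=0.2)
        tree = nj_tree(dm)
        clusters = threshold_clusters(dm, 0.054)
        with pytest.raises(ValueError):
            consistency_report(tree, clusters, {"a1": "A", "a2": "A"})
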