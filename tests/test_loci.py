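import io

import dendropy
import numpy as np
import pytest

from mhcloci.loci import (DistanceMatrix, constrained_grouping, export_nexus,
                          min_locus_bound, nj_tree, p_distance_matrix)
from mhcloci.simulate import SimConfig, simulate
from mhcloci.validation import GenotypeTable

from _oracles import min_legal_partition_count


class TestPDistance:
    def test_identical(self):
        dm = p_distance_matrix([("a", "ACGT"), ("b", "ACGT")])
        assert dm.get("a", "b") == 0.0

    def test_definitional(self):
        dm = p_distance_matrix([("a", "AAAA"), ("b", "AAAT")])
        assert dm.get("a", "b") == 0.25

    def test_gap_columns_excluded(self):
        # unequal lengths force an aligned gap, which is not compared
        dm = p_distance_matrix([("a", "AAAATTTTCCCC"), ("b", "AAAATTTCCCC")])
        assert dm.get("a", "b") == 0.0

    def test_within_locus_closer_than_between(self):
        """Simulated allele pools: mean within-locus distance is below the
        mean between-locus distance, by construction of the generator."""
        for seed in range(1, 11):
            res = simulate(SimConfig(seed=seed, clone_depth=(1, 1),
                                     make_cdna_clones=False,
                                     make_gdna_clones=False))
            items = [(al.name, al.cdna) for al in res.truth.alleles]
            locus_of = {al.name: al.locus for al in res.truth.alleles}
            dm = p_distance_matrix(items)
            within, between = [], []
            n = len(dm.labels)
            for i in range(n):
                for j in range(i + 1, n):
                    d = dm.values[i, j]
                    same = locus_of[dm.labels[i]] == locus_of[dm.labels[j]]
                    (within if same else between).append(d)
            assert np.mean(within) < np.mean(between)


class TestNjTree:
    def test_needs_three_labels(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_three_taxa(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]])
        newick = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_four_taxon_additive_topology_recovered(self):
        """On a matrix additive on ((A,B),(C,D)) the AB|CD split is the
        unique one consistent with the four-point condition, and NJ finds
        it."""
        # branch lengths: A=1, B=2, C=3, D=1, internal=1
        d = {("A", "B"): 3, ("C", "D"): 4, ("A", "C"): 5,
             ("A", "D"): 3, ("B", "C"): 6, ("B", "D"): 4}
        labels = ("A", "B", "C", "D")
        mat = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    v = d[(x, y)] if (x, y) in d else d[(y, x)]
                    mat[i, j] = mat[j, i] = v
        # oracle: four-point condition picks the split pairing the two
        # smallest sums
        sums = {
            "AB|CD": d[("A", "B")] + d[("C", "D")],
            "AC|BD": d[("A", "C")] + d[("B", "D")],
            "AD|BC": d[("A", "D")] + d[("B", "C")],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        newick = nj_tree(DistanceMatrix(labels, mat))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        splits = {frozenset(
            t.label for t in bp.leafset_taxa(tree.taxon_namespace))
            for bp in tree.bipartition_encoding}
        assert frozenset({"A", "B"}) in splits or \
            frozenset({"C", "D"}) in splits

    def test_ultrametric_cherries_recovered(self):
        labels = ("a1", "a2", "b1", "b2", "c")
        mat = np.full((5, 5), 1.0)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 0.1
        mat[2, 3] = mat[3, 2] = 0.1
        newick = nj_tree(DistanceMatrix(labels, mat))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        splits = {frozenset(
            t.label for t in bp.leafset_taxa(tree.taxon_namespace))
            for bp in tree.bipartition_encoding}
        all_taxa = frozenset(labels)
        for cherry in (frozenset({"a1", "a2"}), frozenset({"b1", "b2"})):
            assert cherry in splits or (all_taxa - cherry) in splits

    def test_newick_round_trips_with_same_leaf_set(self, sim42):
        items = [(al.name, al.cdna) for al in sim42.truth.alleles]
        dm = p_distance_matrix(items)
        newick = nj_tree(dm)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == set(dm.labels)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestMinLocusBound:
    @pytest.mark.parametrize("counts,expected", [
        ({"i1": 8}, 4),
        ({"i1": 1}, 1),
        ({"a": 2, "b": 3, "c": 5, "d": 8, "e": 7}, 4),
    ])
    def test_bound(self, counts, expected):
        table = GenotypeTable({
            ind: {f"{ind}_al{k}" for k in range(c)}
            for ind, c in counts.items()})
        assert min_locus_bound(table) == expected

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            min_locus_bound(GenotypeTable({}))


def _tight_pairs_matrix(n_pairs, within=0.01, between=0.3):
    n = 2 * n_pairs
    mat = np.full((n, n), between)
    np.fill_diagonal(mat, 0.0)
    labels = []
    for p in range(n_pairs):
        labels += [f"p{p}x", f"p{p}y"]
        mat[2 * p, 2 * p + 1] = mat[2 * p + 1, 2 * p] = within
    return DistanceMatrix(tuple(labels), mat)


class TestConstrainedGrouping:
    def test_eight_alleles_of_one_individual_in_four_pairs(self):
        """Eight alleles of a single diploid individual forming four tight
        pairs resolve to four groups of two: at least four loci."""
        dm = _tight_pairs_matrix(4)
        table = GenotypeTable({"no3": set(dm.labels)})
        g = constrained_grouping(dm, table)
        assert sorted(len(gr) for gr in g.groups) == [2, 2, 2, 2]
        assert g.min_locus_estimate == 4
        assert g.unassigned == ()

    def test_single_allele(self):
        dm = DistanceMatrix(("a",), np.zeros((1, 1)))
        table = GenotypeTable({"i1": {"a"}})
        g = constrained_grouping(dm, table)
        assert g.groups == (("a",),)
        assert g.min_locus_estimate == 1

    def test_allele_missing_from_table_is_an_error(self):
        dm = _tight_pairs_matrix(1)
        with pytest.raises(ValueError):
            constrained_grouping(dm, GenotypeTable({"i": {"p0x"}}))

    def test_greedy_deadlock_resolved_to_minimum(self):
        """An input where pairwise merging stalls at three groups but a
        legal two-group partition exists: the exact refinement finds it."""
        labels = ("a1", "a2", "a3", "a4", "a5", "a6")
        mat = np.full((6, 6), 0.5)
        np.fill_diagonal(mat, 0.0)
        for i, j in ((0, 1), (2, 3), (4, 5)):
            mat[i, j] = mat[j, i] = 0.01
        dm = DistanceMatrix(labels, mat)
        carriers = {
            "a1": {"A"}, "a2": {"A", "B"}, "a3": {"A", "C"},
            "a4": {"C"}, "a5": {"B"}, "a6": {"B", "C"},
        }
        table = GenotypeTable({
            ind: {l for l, cs in carriers.items() if ind in cs}
            for ind in "ABC"})
        g = constrained_grouping(dm, table, outlier_quantile=1.0)
        assert len(g.groups) == 2
        assert len(g.groups) == min_legal_partition_count(labels, carriers)

    def test_outlier_singleton_moved_to_unassigned(self):
        """A singleton far from every other allele is reported unassigned
        rather than forced into a group."""
        base = _tight_pairs_matrix(4, within=0.01, between=0.06)
        n = 9
        mat = np.zeros((n, n))
        mat[:8, :8] = base.values
        mat[8, :8] = mat[:8, 8] = 0.3
        labels = base.labels + ("lonely",)
        dm = DistanceMatrix(labels, mat)
        table = GenotypeTable({"i1": set(base.labels), "i2": {"lonely"}})
        g = constrained_grouping(dm, table, outlier_quantile=0.7)
        assert g.unassigned == ("lonely",)
        assert all("lonely" not in gr for gr in g.groups)

    def test_estimate_never_below_bound(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            labels = tuple(f"a{i}" for i in range(n))
            mat = rng.random((n, n))
            mat = (mat + mat.T) / 2
            np.fill_diagonal(mat, 0.0)
            inds = [f"i{k}" for k in range(int(rng.integers(1, 4)))]
            carriers = {
                l: set(rng.choice(inds,
                                  size=int(rng.integers(1, len(inds) + 1)),
                                  replace=False))
                for l in labels}
            table = GenotypeTable({
                ind: {l for l in labels if ind in carriers[l]}
                for ind in inds})
            dm = DistanceMatrix(labels, mat)
            g = constrained_grouping(dm, table)
            assert g.min_locus_estimate >= min_locus_bound(table)


def test_nexus_export_contains_data_and_mrbayes_blocks():
    text = export_nexus([("al1", "ACGT"), ("al2", "ACGA")])
    assert text.startswith("#NEXUS")
    assert "ntax=2 nchar=4" in text
    assert "begin mrbayes;" in text
    assert "nst=6 rates=gamma" in text
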