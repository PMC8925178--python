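import numpy as np
import pytest

from _oracles import (enumerate_topologies, tree_bipartitions,
                      tree_distance_matrix)
from genefam.core_io import Alignment, SequenceSet
from genefam.phylo import (DistanceMatrix, assign_subfamilies,
                           bootstrap_support, distance_matrix,
                           neighbor_joining, p_distance, progressive_align)


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("ACGT", "ACGT", 0.0), ("AA", "AG", 0.5), ("A-", "AG", 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_poisson_correction(self):
        assert p_distance("AA", "AG", "poisson") == pytest.approx(
            -np.log(0.5)
        )

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("--", "AG")

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            p_distance("AAA", "AA")


class TestNeighborJoining:
    additive = DistanceMatrix(
        list("ABCD"),
        np.array([[0, 3, 8, 9], [3, 0, 7, 8], [8, 7, 0, 3], [9, 8, 3, 0]],
                 float),
    )

    def test_four_taxon_topology(self):
        tree = neighbor_joining(self.additive)
        assert tree.bipartitions() == {frozenset({"C", "D"})}  # AB|CD

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 4.0})

    def test_additivity_reproduced(self):
        tree = neighbor_joining(self.additive)
        plm = tree.path_length_matrix()
        order = [plm.labels.index(x) for x in "ABCD"]
        assert np.allclose(plm.d[np.ix_(order, order)], self.additive.d,
                           atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = self.additive.d.copy()
        d[0, 1] = 99.0
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(list("ABCD"), d))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 6
            d = rng.uniform(0.1, 2.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], d))
            assert all(node.length >= 0 for node in tree.root.walk())
            assert ":-" not in tree.newick()

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_recovers_all_enumerated_topologies(self, n_taxa):
        """NJ on an exactly additive matrix recovers the generating tree."""
        labels = [f"t{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(42)
        for topo in enumerate_topologies(labels):
            d = tree_distance_matrix(topo, labels, rng)
            nj = neighbor_joining(DistanceMatrix(labels, d))
            assert nj.bipartitions() == tree_bipartitions(topo, labels)


class TestBootstrap:
    def _alignment(self):
        # t1/t2 share a distinctive block; others diverge independently
        rows = [
            ("t1", "AAAAAAAAAACCCCCCCCCC"),
            ("t2", "AAAAAAAAAACCCCCCCCCG"),
            ("t3", "TTTTTGGGGGACGTACGTAC"),
            ("t4", "GGGGGTTTTTCATGCATGCA"),
            ("t5", "CGCGCGCGCGTATATATATA"),
        ]
        return Alignment(rows, "nucleotide")

    def test_unanimous_alignment_gets_full_support(self):
        # every column supports t1t2 | t3t4: resampling cannot break the split
        rows = [("t1", "A" * 20), ("t2", "A" * 20),
                ("t3", "C" * 20), ("t4", "C" * 20)]
        tree = bootstrap_support(Alignment(rows, "nucleotide"),
                                 replicates=50, seed=1)
        supports = [n.support for n in tree.root.walk()
                    if n.support is not None]
        assert supports and all(s == 50 for s in supports)

    def test_same_seed_reproduces_supports(self):
        aln = self._alignment()
        t1 = bootstrap_support(aln, replicates=60, seed=9)
        t2 = bootstrap_support(aln, replicates=60, seed=9)
        assert t1.newick() == t2.newick()

    def test_planted_clade_strongly_supported(self):
        tree = bootstrap_support(self._alignment(), replicates=100, seed=3)
        support = {
            frozenset(l.name for l in n.leaves()): n.support
            for n in tree.root.walk() if n.support is not None
        }
        # canonical side excludes the smallest label t1
        clade = frozenset({"t3", "t4", "t5"})
        assert support.get(clade, 0) >= 95

    def test_supports_within_bounds_and_row_order_invariant(self):
        aln = self._alignment()
        shuffled = Alignment(list(reversed(aln.rows)), "nucleotide")
        def table(t):
            return {
                frozenset(l.name for l in n.leaves()): n.support
                for n in t.root.walk() if n.support is not None
            }
        t1 = table(bootstrap_support(aln, replicates=80, seed=5))
        t2 = table(bootstrap_support(shuffled, replicates=80, seed=5))
        assert all(0 <= s <= 80 for s in t1.values())
        shared = set(t1) & set(t2)
        assert shared and all(t1[k] == t2[k] for k in shared)

    def test_invalid_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._alignment(), replicates=0, seed=1)


class TestSubfamilies:
    def _clustered_tree(self, n_clusters=7, size=4, seed=0):
        rng = np.random.default_rng(seed)
        labels, blocks = [], []
        for c in range(n_clusters):
            for k in range(size):
                labels.append(f"c{c}_m{k}")
                blocks.append(c)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.1 if blocks[i] == blocks[j] else 2.0
                d[i, j] = d[j, i] = base + rng.uniform(0, 0.02)
        return labels, blocks, neighbor_joining(DistanceMatrix(labels, d))

    def test_anchor_labels_propagate_within_clusters(self):
        labels, blocks, tree = self._clustered_tree()
        anchors = {f"c{c}_m0": f"VQ{c + 1}" for c in range(7)}
        assigned = assign_subfamilies(tree, anchors)
        for lbl, block in zip(labels, blocks):
            assert assigned[lbl] == f"VQ{block + 1}"

    def test_sister_anchor(self):
        dm = DistanceMatrix(
            ["x", "a1", "b1"],
            np.array([[0, 0.1, 2.0], [0.1, 0, 2.0], [2.0, 2.0, 0]], float),
        )
        tree = neighbor_joining(dm)
        assert assign_subfamilies(tree, {"a1": "VQV"})["x"] == "VQV"

    def test_conflicting_anchors_unassigned(self):
        labels, _, tree = self._clustered_tree(n_clusters=2, size=3)
        anchors = {"c0_m0": "VQI", "c0_m1": "VQII"}
        assigned = assign_subfamilies(tree, anchors)
        assert assigned["c0_m2"] == "UNASSIGNED"

    def test_no_anchors_error(self):
        _, _, tree = self._clustered_tree(n_clusters=2, size=3)
        with pytest.raises(ValueError):
            assign_subfamilies(tree, {})


class TestProgressiveAligner:
    def test_rows_ungap_to_inputs(self):
        seqs = SequenceSet(
            {"a": "MKVLITGAC", "b": "MKVLGAC", "c": "MKITGAC"}, "protein"
        )
        aln = progressive_align(seqs)
        assert {rid for rid, _ in aln.rows} == set(seqs.records)
        for rid, row in aln.rows:
            assert row.replace("-", "") == seqs[rid]
        assert len({len(r) for _, r in aln.rows}) == 1

    def test_identical_sequences_align_without_gaps(self):
        seqs = SequenceSet({"a": "MKVLIT", "b": "MKVLIT", "c": "MKVLIT"},
                           "protein")
        aln = progressive_align(seqs)
        assert all(row == "MKVLIT" for _, row in aln.rows)
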