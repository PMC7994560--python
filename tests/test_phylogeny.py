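import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from famkit.io import AlignedBlock
from famkit.phylogeny import (
    DistanceMatrix,
    PhyloConfig,
    assign_subfamilies,
    bootstrap_support,
    nj_tree,
    p_distance,
)
from famkit.simulate import SimSpec, sim_tree_distances


def patristic(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[frozenset({a.label, b.label})] = pdm.patristic_distance(a, b)
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b) == 0


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = AlignedBlock(("a", "b", "c"), ("ACDE", "ACDE", "ACDE"))
        dm = p_distance(aln)
        assert np.allclose(dm.d, 0.0)

    def test_one_of_three_mismatches(self):
        aln = AlignedBlock(("a", "b", "c"), ("ACD", "ACE", "ACD"))
        dm = p_distance(aln)
        assert dm.value("a", "b") == pytest.approx(1 / 3)

    def test_pairwise_deletion_drops_gap_columns(self):
        aln = AlignedBlock(("a", "b", "c"), ("A-C", "AGC", "AGC"))
        dm = p_distance(aln)
        assert dm.value("a", "b") == 0.0

    def test_no_comparable_columns_is_error(self):
        aln = AlignedBlock(("a", "b", "c"), ("A--", "--C", "AGC"))
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        ids = ("A", "B", "C")
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(ids, d))
        # star tree: la = (dAB+dAC-dBC)/2 = 0, lb = 2, lc = 3
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_example(self):
        """((A:1,B:2):1,(C:3,D:1)) -> AB|CD with exact branch lengths."""
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(ids, d))
        truth = dendropy.Tree.get(
            data="((A:1,B:2):1,(C:3,D:1));", schema="newick"
        )
        assert same_topology(tree, truth)
        rec = patristic(tree)
        for pair, expected in {
            frozenset("AB"): 3, frozenset("AC"): 5, frozenset("AD"): 3,
            frozenset("BC"): 6, frozenset("BD"): 4, frozenset("CD"): 4,
        }.items():
            assert rec[pair] == pytest.approx(expected)

    def test_four_point_condition_identifies_quartet(self):
        """Brute force over the 3 quartet topologies: AB|CD has the minimal
        sum d(A,B)+d(C,D), so NJ must return that split."""
        d = {
            ("A", "B"): 3, ("C", "D"): 4, ("A", "C"): 5,
            ("B", "D"): 4, ("A", "D"): 3, ("B", "C"): 6,
        }
        sums = {
            "AB|CD": d[("A", "B")] + d[("C", "D")],
            "AC|BD": d[("A", "C")] + d[("B", "D")],
            "AD|BC": d[("A", "D")] + d[("B", "C")],
        }
        assert min(sums, key=sums.get) == "AB|CD"

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_trees(self, seed):
        """Random 8-leaf trees with path-length distances are recovered
        exactly (topology and all patristic distances)."""
        truth, dm = sim_tree_distances(SimSpec(rng_seed=seed, n_leaves=8))
        tree = nj_tree(dm)
        assert same_topology(tree, truth)
        rec = patristic(tree)
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1 :]:
                assert rec[frozenset({a, b})] == pytest.approx(dm.value(a, b))

    def test_taxon_order_invariance(self):
        truth, dm = sim_tree_distances(SimSpec(rng_seed=99, n_leaves=7))
        perm = np.random.default_rng(0).permutation(len(dm.ids))
        dm2 = DistanceMatrix(
            tuple(dm.ids[i] for i in perm), dm.d[np.ix_(perm, perm)]
        )
        assert same_topology(nj_tree(dm), nj_tree(dm2))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), d)

    def test_branch_lengths_clamped_nonnegative(self):
        rng = np.random.default_rng(5)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = nj_tree(DistanceMatrix(tuple("ABCDEF"), m))
        assert all(e.length >= 0 for e in tree.preorder_edge_iter()
                   if e.length is not None)


class TestBootstrap:
    def test_perfect_split_gets_support_100(self, perfect_split_alignment):
        cfg = PhyloConfig(n_bootstrap=50, rng_seed=1)
        tree = bootstrap_support(perfect_split_alignment, cfg)
        supports = [
            node.edge.support
            for node in tree.preorder_node_iter()
            if getattr(node.edge, "support", None) is not None
        ]
        assert supports == [100.0]

    def test_single_replicate_supports_are_0_or_100(self):
        rng = np.random.default_rng(2)
        rows = tuple(
            "".join(rng.choice(list("ACDE"), size=30)) for _ in range(6)
        )
        aln = AlignedBlock(tuple("ABCDEF"), rows)
        tree = bootstrap_support(aln, PhyloConfig(n_bootstrap=1, rng_seed=3))
        for node in tree.preorder_node_iter():
            support = getattr(node.edge, "support", None)
            if support is not None:
                assert support in (0.0, 100.0)

    def test_seed_reproducibility(self, perfect_split_alignment):
        cfg = PhyloConfig(n_bootstrap=20, rng_seed=7)
        t1 = bootstrap_support(perfect_split_alignment, cfg)
        t2 = bootstrap_support(perfect_split_alignment, cfg)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_support_stability_across_seeds(self):
        """At a few hundred replicates, supports vary by only a few points
        between seeds on a fixed synthetic alignment."""
        rng = np.random.default_rng(4)
        base = ("A" * 40, "A" * 40, "C" * 40, "C" * 40, "G" * 40, "G" * 40)
        noisy = tuple(
            "".join(
                ch if rng.random() > 0.1
                else str(rng.choice(list("ACDEFG"))) for ch in row
            )
            for row in base
        )
        aln = AlignedBlock(tuple("ABCDEF"), noisy)

        def supports(seed: int) -> dict[frozenset, float]:
            tree = bootstrap_support(
                aln, PhyloConfig(n_bootstrap=200, rng_seed=seed)
            )
            out = {}
            leaves = frozenset(aln.ids)
            for node in tree.preorder_node_iter():
                s = getattr(node.edge, "support", None)
                if s is None:
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                out[min(side, leaves - side, key=sorted)] = s
            return out

        s1, s2 = supports(11), supports(22)
        for key in s1.keys() & s2.keys():
            assert abs(s1[key] - s2[key]) <= 10


class TestAssignSubfamilies:
    def _tree(self, newick: str) -> dendropy.Tree:
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_query_sister_to_single_anchor(self):
        tree = self._tree("((q1:1,ANC1:1):1,(ANC2:1,ANC3:1):1,out:3);")
        anchors = {"ANC1": "III f", "ANC2": "I a", "ANC3": "I a", "out": "X"}
        assert assign_subfamilies(tree, anchors)["q1"] == "III f"

    def test_mixed_anchor_clade_is_orphan(self):
        tree = self._tree("((q1:1,(ANC1:1,ANC2:1):1):1,ANC3:1,ANC4:4);")
        anchors = {"ANC1": "I a", "ANC2": "I b", "ANC3": "I a", "ANC4": "I b"}
        assert assign_subfamilies(tree, anchors)["q1"] == "orphan"

    def test_no_anchors_rejected(self):
        tree = self._tree("((q1:1,q2:1):1,q3:1,q4:1);")
        with pytest.raises(ValueError, match="anchor"):
            assign_subfamilies(tree, {"zzz": "I a"})

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_single_label_clades_recovered(self, seed):
        """Queries planted inside single-label anchor clades always get
        the planted label."""
        rng = np.random.default_rng(seed)
        labels = ["I a", "III f", "V b"]
        parts = []
        truth = {}
        for k, lab in enumerate(labels):
            q = f"q{k}"
            anchors = [f"A{k}x{j}" for j in range(2)]
            inner = f"({q}:1,{anchors[0]}:1)"
            parts.append(f"(({inner}:1,{anchors[1]}:1):{rng.uniform(1, 2):.3f})")
            truth[q] = lab
        newick = f"({parts[0]},{parts[1]},{parts[2]});"
        tree = self._tree(newick)
        anchor_map = {
            f"A{k}x{j}": lab
            for k, lab in enumerate(labels)
            for j in range(2)
        }
        assignment = assign_subfamilies(tree, anchor_map)
        for q, lab in truth.items():
            assert assignment[q] == lab
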