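"""Distance matrices, neighbor joining, Robinson-Foulds, newick I/O."""

import numpy as np
import pytest

from mitomarker.align_variants import MultipleAlignment
from mitomarker.errors import AlignmentError, TreeError
from mitomarker.phylo import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    concat_alignment,
    newick_read,
    newick_write,
    nj_tree,
    p_distance_matrix,
    rf_distance,
    write_phylip_matrix,
)

from oracles import (
    adjacency_to_newick,
    enumerate_unrooted_topologies,
    tree_splits_by_connectivity,
)


def random_binary_tree(rng, labels):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=x, length=float(rng.uniform(0.1, 1.0))) for x in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))] + [parent]
    return PhyloTree(root=TreeNode(children=nodes))


def additive_matrix(tree):
    """Path-length distances between all leaf pairs (independent traversal)."""
    leaves = tree.leaf_names()
    paths = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    walk(tree.root, [])
    # distance = sum of branch lengths not shared between the two paths
    def dist(x, y):
        px = [id(n) for n, _ in paths[x]]
        py = [id(n) for n, _ in paths[y]]
        shared = 0
        for a, b in zip(px, py):
            if a == b:
                shared += 1
            else:
                break
        return sum(l for _, l in paths[x][shared:]) + sum(l for _, l in paths[y][shared:])

    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(leaves[i], leaves[j])
    return DistanceMatrix(taxa=leaves, values=D)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT"] * 3)
        dm = p_distance_matrix(aln)
        assert np.allclose(dm.values, 0)

    def test_single_site_difference(self):
        rows = ["A" * 222, "A" * 100 + "G" + "A" * 121]
        dm = p_distance_matrix(MultipleAlignment(["x", "y"], rows))
        assert dm.get("x", "y") == pytest.approx(1 / 222)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(4)
        rows = ["".join("ACGT-"[i] for i in rng.integers(0, 5, 80)) for _ in range(4)]
        taxa = list("abcd")
        aln = MultipleAlignment(taxa, rows)
        dm = p_distance_matrix(aln, gap_mode="pairwise_deletion")
        for i in range(4):
            for j in range(i + 1, 4):
                diff = total = 0
                for x, y in zip(rows[i], rows[j]):
                    if x in "ACGT" and y in "ACGT":
                        total += 1
                        diff += x != y
                assert dm.values[i, j] == pytest.approx(diff / total)

    def test_jukes_cantor_correction(self):
        rows = ["A" * 100, "A" * 90 + "G" * 10]
        dm = p_distance_matrix(MultipleAlignment(["x", "y"], rows), model="jc")
        assert dm.get("x", "y") == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))

    def test_no_comparable_columns(self):
        aln = MultipleAlignment(["a", "b"], ["A---", "---T"])
        with pytest.raises(AlignmentError, match="comparable"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(D)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_five_taxon_additive_recovery(self):
        rng = np.random.default_rng(0)
        truth = random_binary_tree(rng, list("abcde"))
        tree = nj_tree(additive_matrix(truth))
        assert rf_distance(tree, truth)[0] == 0

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_consistency(self, n):
        """NJ recovers the generating topology from exact additive distances."""
        rng = np.random.default_rng(100 + n)
        for _ in range(8):
            truth = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            tree = nj_tree(additive_matrix(truth))
            assert rf_distance(tree, truth)[0] == 0

    def test_identical_taxa_coalesce_deterministically(self):
        # two identical taxa plus two distinct ones; the zero pair must
        # form its own cherry regardless of the rest of the matrix
        D = np.array(
            [[0, 0, 0.4, 0.5], [0, 0, 0.4, 0.5], [0.4, 0.4, 0, 0.3], [0.5, 0.5, 0.3, 0]]
        )
        tree = nj_tree(DistanceMatrix(["x1", "x2", "y", "z"], D))
        assert frozenset(["y", "z"]) in tree.bipartitions() or frozenset(
            ["x1", "x2"]
        ) in tree.bipartitions()


class TestRobinsonFoulds:
    def test_self_distance_zero(self):
        t = newick_read("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, t) == (0, 0.0)

    def test_four_taxon_alternatives(self):
        t1 = newick_read("((a:1,b:1):1,c:1,d:1);")
        t2 = newick_read("((a:1,c:1):1,b:1,d:1);")
        assert rf_distance(t1, t2)[0] == 2
        assert rf_distance(t1, t2)[1] == 1.0

    def test_leaf_set_mismatch(self):
        t1 = newick_read("((a:1,b:1):1,c:1,d:1);")
        t2 = newick_read("((a:1,b:1):1,c:1,e:1);")
        with pytest.raises(TreeError, match="leaf sets differ"):
            rf_distance(t1, t2)

    def test_matches_connectivity_oracle_n5(self):
        """RF equals the brute-force split comparison on all 5-taxon topologies."""
        labels = list("abcde")
        trees = enumerate_unrooted_topologies(labels)
        assert len(trees) == 15
        splits = [tree_splits_by_connectivity(adj, labels) for adj in trees]
        parsed = [newick_read(adjacency_to_newick(adj, labels)) for adj in trees]
        for i in range(len(trees)):
            for j in range(len(trees)):
                expected = len(splits[i] ^ splits[j])
                assert rf_distance(parsed[i], parsed[j])[0] == expected

    def test_metric_properties(self):
        rng = np.random.default_rng(9)
        trees = [random_binary_tree(rng, list("abcdef")) for _ in range(6)]
        for t1 in trees:
            for t2 in trees:
                d12 = rf_distance(t1, t2)[0]
                assert d12 == rf_distance(t2, t1)[0]
                assert d12 >= 0
                for t3 in trees:
                    assert d12 <= rf_distance(t1, t3)[0] + rf_distance(t3, t2)[0]


class TestNewick:
    @pytest.mark.parametrize(
        "text",
        [
            "(a:1.000000,b:1.000000,(c:1.000000,d:1.000000):1.000000);",
            "('taxon one':0.500000,'b''s':0.250000,c:0.125000);",
        ],
    )
    def test_round_trip(self, text):
        tree = newick_read(text)
        assert newick_write(tree) == text

    def test_unbalanced_parentheses(self):
        with pytest.raises(TreeError):
            newick_read("((a:1,b:1):1;")

    def test_50_taxon_round_trip_preserves_topology(self):
        rng = np.random.default_rng(2)
        tree = random_binary_tree(rng, [f"t{i:02d}" for i in range(50)])
        back = newick_read(newick_write(tree))
        assert rf_distance(tree, back)[0] == 0
        for a, b in zip(sorted(tree.root.leaves(), key=lambda x: x.name),
                        sorted(back.root.leaves(), key=lambda x: x.name)):
            assert b.length == pytest.approx(a.length, abs=1e-6)

    def test_missing_semicolon(self):
        with pytest.raises(TreeError):
            newick_read("(a,b)")


class TestConcatenation:
    def test_width_is_sum_of_blocks(self):
        taxa = ["x", "y", "z"]
        b1 = MultipleAlignment(taxa, ["A" * 222] * 3)
        b2 = MultipleAlignment(taxa, ["C" * 267] * 3)
        out = concat_alignment([b1, b2], ["atp9", "nad4l"])
        assert out.width == 489
        assert out.blocks == [("atp9", 222), ("nad4l", 267)]

    def test_single_block_identity(self):
        b = MultipleAlignment(["x", "y"], ["ACGT", "AGGT"])
        out = concat_alignment([b])
        assert out.rows == b.rows

    def test_missing_taxon_rejected(self):
        b1 = MultipleAlignment(["x", "y"], ["AC", "AC"])
        b2 = MultipleAlignment(["x", "z"], ["GT", "GT"])
        with pytest.raises(AlignmentError, match="mismatch"):
            concat_alignment([b1, b2])

    def test_fifteen_simulated_blocks(self, small_collection):
        from mitomarker.marker_screen import core_gene_supermatrix
        from mitomarker.synthetic_data import DEFAULT_GENE_LENGTHS

        records, _ = small_collection
        sm = core_gene_supermatrix(records)
        assert [name for name, _ in sm.blocks] == sorted(DEFAULT_GENE_LENGTHS)
        assert sm.width == sum(width for _, width in sm.blocks)
        # substitution-only genes: every ungapped row carries the full
        # table length for each gene
        for row in sm.rows:
            assert len(row.replace("-", "")) == sum(DEFAULT_GENE_LENGTHS.values())


def test_phylip_matrix_output():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
    text = write_phylip_matrix(dm)
    assert text.splitlines()[0] == "2"
    assert "0.500000" in text
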