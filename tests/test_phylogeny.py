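"""Supermatrix assembly, distances, neighbor joining (with a least-squares
enumeration oracle), bootstrap supports, the gene-content tree and
Robinson-Foulds distances."""
import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from panforge.phylogeny import (
    Alignment,
    bootstrap_support,
    concatenate_single_copy,
    distance_matrix,
    filter_columns,
    manhattan_tree,
    nj_tree,
    rf_distance,
    tree_splits,
)


class TestConcatenate:
    def test_lengths_add(self):
        fams = {
            "f1": {"a": "MKLVW", "b": "MKLVW"},
            "f2": {"a": "AAAAAAA", "b": "AAAAAAW"},
        }
        aln = concatenate_single_copy(fams, ["a", "b"])
        assert aln.length == 12
        assert aln.blocks == [("f1", 0, 5), ("f2", 5, 12)]

    def test_single_family_identity(self):
        fams = {"f1": {"a": "MKL", "b": "MKW"}}
        aln = concatenate_single_copy(fams, ["a", "b"])
        assert aln.seqs == ["MKL", "MKW"]

    def test_no_families_rejected(self):
        with pytest.raises(ValueError):
            concatenate_single_copy({}, ["a"])

    def test_missing_taxon_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            concatenate_single_copy({"f1": {"a": "MK"}}, ["a", "b"])


class TestFilterColumns:
    def test_clean_alignment_unchanged(self):
        aln = Alignment(["a", "b"], ["MKL", "MKL"])
        out, removed = filter_columns(aln)
        assert removed == 0 and out.seqs == aln.seqs

    def test_gappy_column_removed(self):
        aln = Alignment(list("abcd"), ["M-KL", "M-KL", "M-KL", "MAKL"])
        out, removed = filter_columns(aln, max_gap_fraction=0.5)
        assert removed == 1
        assert out.length == 3

    def test_unconserved_column_removed(self):
        aln = Alignment(list("abcd"), ["MA", "MC", "MD", "ME"])
        out, removed = filter_columns(aln, min_conservation=0.5)
        assert removed == 1 and out.length == 1

    def test_all_removed_rejected(self):
        aln = Alignment(list("abcd"), ["A", "C", "D", "E"])
        with pytest.raises(ValueError):
            filter_columns(aln)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["MKLVW", "MKLVW"])
        dm = distance_matrix(aln)
        assert dm["a", "b"] == 0

    def test_poisson_correction(self):
        aln = Alignment(["a", "b"], ["MKLV", "MKAA"])  # p = 0.5
        dm = distance_matrix(aln, model="poisson")
        assert dm["a", "b"] == pytest.approx(np.log(2))

    def test_symmetry_zero_diagonal_random(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDEFG"), 30)) for _ in range(4)]
        dm = distance_matrix(Alignment(list("wxyz"), rows))
        d = dm.data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_saturated_poisson_rejected(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError):
            distance_matrix(aln, model="poisson")


def random_tree(n_leaves, rng):
    """Random binary topology with positive branch lengths via sequential
    leaf attachment; returns dendropy tree with taxa t0..t{n-1}."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    a, b = dendropy.Node(), dendropy.Node()
    a.taxon, b.taxon = ns.get_taxon("t0"), ns.get_taxon("t1")
    tree.seed_node.add_child(a)
    tree.seed_node.add_child(b)
    for e in (a.edge, b.edge):
        e.length = float(rng.uniform(0.2, 1.5))
    for k in range(2, n_leaves):
        edges = [
            e for e in tree.preorder_edge_iter()
            if e.length is not None
        ]
        target = edges[rng.integers(len(edges))]
        head = target.head_node
        parent = head.parent_node
        split = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(split)
        frac = float(rng.uniform(0.2, 0.8))
        split.edge.length = target.length * frac
        split.add_child(head)
        head.edge.length = target.length * (1 - frac)
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(f"t{k}")
        leaf.edge.length = float(rng.uniform(0.2, 1.5))
        split.add_child(leaf)
    tree.is_rooted = False
    return tree


def additive_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(d, labels)


def ls_enumeration_topology(dm):
    """Least-squares oracle for 4 or 5 taxa: enumerate all unrooted
    topologies, fit branch lengths by unconstrained least squares on the
    path-incidence system, return the split set of the best-fitting tree."""
    labels = list(dm.ids)
    n = len(labels)
    assert n in (4, 5)
    newicks = []
    if n == 4:
        a, b, c, d = labels
        newicks = [
            f"(({a},{b}),({c},{d}));",
            f"(({a},{c}),({b},{d}));",
            f"(({a},{d}),({b},{c}));",
        ]
    else:
        # all 15 unrooted 5-leaf topologies: choose the cherry pair plus the
        # attachment of the fifth taxon onto one of five edges of the
        # 4-leaf tree; enumerate distinct split sets via dendropy
        for quartet in itertools.permutations(labels):
            a, b, c, d, e = quartet
            newicks.append(f"((({a},{b}),{c}),({d},{e}));")
        newicks = list(dict.fromkeys(newicks))

    best, best_err = None, np.inf
    seen_splits = set()
    for nwk in newicks:
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = False
        splits = frozenset(tree_splits(tree))
        if splits in seen_splits:
            continue
        seen_splits.add(splits)
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        pairs = list(itertools.combinations(labels, 2))
        rows, y = [], []
        leaf_of = {l.taxon.label: l for l in tree.leaf_node_iter()}
        for x, z in pairs:
            path = set()
            seen_nodes = set()
            node = leaf_of[x]
            while node is not None:
                seen_nodes.add(id(node))
                node = node.parent_node
            node = leaf_of[z]
            climb = []
            while id(node) not in seen_nodes:
                climb.append(node)
                node = node.parent_node
            meet = node
            node = leaf_of[x]
            side = []
            while node is not meet:
                side.append(node)
                node = node.parent_node
            on_path = {id(n) for n in climb + side}
            rows.append([1.0 if id(e.head_node) in on_path else 0.0 for e in edges])
            y.append(dm[x, z])
        coef, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        err = float(np.sum((np.array(rows) @ coef - y) ** 2))
        if err < best_err - 1e-12:
            best, best_err = splits, err
    return best


class TestNeighborJoining:
    def test_additive_four_leaf_exact(self):
        rng = np.random.default_rng(4)
        tree = random_tree(4, rng)
        dm = additive_matrix(tree)
        recovered = nj_tree(dm)
        assert rf_distance(tree, recovered) == 0
        # branch lengths: patristic distances reproduce the input exactly
        rec_dm = additive_matrix(recovered)
        assert np.allclose(rec_dm.data, dm.data)

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_matches_least_squares_enumeration(self, n_leaves):
        rng = np.random.default_rng(10 + n_leaves)
        for _ in range(5):
            tree = random_tree(n_leaves, rng)
            dm = additive_matrix(tree)
            assert tree_splits(nj_tree(dm)) == ls_enumeration_topology(dm)

    def test_consistency_on_random_trees(self):
        """NJ recovers the generating topology from any additive matrix."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            tree = random_tree(n, rng)
            assert rf_distance(tree, nj_tree(additive_matrix(tree))) == 0

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float),
                            ["x", "y", "z"])
        tree = nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"x": 1.0, "y": 1.0, "z": 2.0}

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        tree = random_tree(6, rng)
        dm = additive_matrix(tree)
        base_splits = tree_splits(nj_tree(dm))
        perm = list(rng.permutation(list(dm.ids)))
        d2 = DistanceMatrix(
            np.array([[dm[a, b] for b in perm] for a in perm]), perm
        )
        assert tree_splits(nj_tree(d2)) == base_splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


class TestBootstrap:
    @staticmethod
    def separated_alignment(seed=1, n_cols=300):
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        base = rng.choice(alphabet, n_cols)
        other = base.copy()
        flip = rng.choice(n_cols, n_cols // 2, replace=False)
        other[flip] = rng.choice(alphabet, len(flip))

        def noisy(b):
            row = b.copy()
            idx = rng.choice(n_cols, 6, replace=False)
            row[idx] = rng.choice(alphabet, 6)
            return "".join(row)

        return Alignment(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            [noisy(base), noisy(base), noisy(base),
             noisy(other), noisy(other), noisy(other)],
        )

    def test_supports_in_range_and_deterministic(self):
        aln = self.separated_alignment()
        t1 = bootstrap_support(aln, n_reps=30, seed=7)
        t2 = bootstrap_support(aln, n_reps=30, seed=7)
        s1 = sorted(n.label for n in t1.preorder_internal_node_iter() if n.label)
        s2 = sorted(n.label for n in t2.preorder_internal_node_iter() if n.label)
        assert s1 == s2
        assert all(0 <= float(s) <= 100 for s in s1)

    def test_clear_clade_split_gets_high_support(self):
        aln = self.separated_alignment(seed=2)
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        target = frozenset({"b1", "b2", "b3"})
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        support = None
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node or node.label is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if side in (target, frozenset(labels - target)):
                support = float(node.label)
        assert support is not None and support >= 95


class TestManhattanTree:
    def test_binary_manhattan_equals_hamming(self):
        m = pd.DataFrame({"g1": [0, 1, 1], "g2": [1, 1, 0], "g3": [1, 0, 1]})
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(m.to_numpy(float).T, metric="cityblock"))
        assert d[0, 1] == 2  # (0,1,1) vs (1,1,0)
        ham = squareform(pdist(m.to_numpy(bool).T, metric="hamming")) * 3
        assert np.allclose(d, ham)

    def test_identical_genomes_zero_terminal_pair(self):
        m = pd.DataFrame({
            "g1": [1, 1, 0], "g2": [1, 1, 0], "g3": [0, 1, 1], "g4": [1, 0, 1],
        })
        tree = manhattan_tree(m)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["g1"] == 0 and lengths["g2"] == 0

    def test_upgma_variant(self):
        m = pd.DataFrame({
            "g1": [1, 1, 0, 0], "g2": [1, 1, 0, 1], "g3": [0, 0, 1, 1],
        })
        tree = manhattan_tree(m, method="upgma")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["g1", "g2", "g3"]


class TestRobinsonFoulds:
    def test_identical_zero(self):
        rng = np.random.default_rng(1)
        t = random_tree(6, rng)
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,c),(b,d));", schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,b),(c,e));", schema="newick")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)
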