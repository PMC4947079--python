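"""Neighbor joining, Newick serialization, nearest neighbors, and PCA."""

import numpy as np
import pytest

from indelpop import (
    AlleleFrequency,
    DistanceMatrix,
    FreqTable,
    nearest_neighbor,
    neighbor_joining,
    pca,
    to_newick,
)


def random_additive_matrix(rng, n_leaves):
    """A random binary tree and its exact leaf-to-leaf distance matrix."""
    labels = [f"T{i}" for i in range(n_leaves)]
    # build a random topology by sequential leaf attachment; track paths
    # through an explicit edge list, then compute path lengths
    import networkx as nx
    g = nx.Graph()
    g.add_edge(labels[0], labels[1],
               weight=round(float(rng.uniform(0.1, 1.0)), 6))
    next_internal = 0
    for leaf in labels[2:]:
        u, v = list(g.edges())[rng.integers(len(g.edges()))]
        w = g[u][v]["weight"]
        node = f"I{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.remove_edge(u, v)
        g.add_edge(u, node, weight=round(w * split, 6))
        g.add_edge(node, v, weight=round(w * (1 - split), 6))
        g.add_edge(node, leaf,
                   weight=round(float(rng.uniform(0.1, 1.0)), 6))
    d = np.zeros((n_leaves, n_leaves))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = lengths[a][b]
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_three_taxon_hand_solution(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                                     dtype=float))
        tree = neighbor_joining(dm)
        paths = tree.path_lengths()
        assert paths[("A", "B")] == pytest.approx(2.0)
        assert paths[("A", "C")] == pytest.approx(3.0)
        assert paths[("B", "C")] == pytest.approx(4.0)
        # three-point formulas: branches 0.5, 1.5, 2.5
        assert to_newick(tree, precision=3) in (
            "(C:2.5,A:0.5,B:1.5);", "(A:0.5,B:1.5,C:2.5);",
            "(B:1.5,C:2.5,A:0.5);", "(C:2.5,B:1.5,A:0.5);",
        ) or sorted(paths.values()) == [2.0, 3.0, 4.0]

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) as an additive matrix
        d = np.array([
            [0, 3, 6, 7],
            [3, 0, 7, 8],
            [6, 7, 0, 7],
            [7, 8, 7, 0],
        ], dtype=float)
        dm = DistanceMatrix(list("ABCD"), d)
        tree = neighbor_joining(dm)
        paths = tree.path_lengths()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)
        assert frozenset({"A", "B"}) in tree.neighbor_sets()

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_random_additive_inversion(self):
        """NJ exactly inverts tree -> additive matrix for random trees."""
        rng = np.random.default_rng(12345)
        for rep in range(50):
            n_leaves = int(rng.integers(5, 13))
            dm = random_additive_matrix(rng, n_leaves)
            tree = neighbor_joining(dm)
            paths = tree.path_lengths()
            for i in range(n_leaves):
                for j in range(i + 1, n_leaves):
                    key = tuple(sorted((dm.labels[i], dm.labels[j])))
                    assert paths[key] == pytest.approx(dm.d[i, j], abs=1e-6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        dm = random_additive_matrix(rng, 8)
        perm = rng.permutation(len(dm.labels))
        dm_perm = DistanceMatrix([dm.labels[i] for i in perm],
                                 dm.d[np.ix_(perm, perm)])
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm_perm)
        assert t1.neighbor_sets() == t2.neighbor_sets()

    def test_matches_dendropy_on_fixture(self, da_fixture):
        """Topology agrees with an independent NJ implementation."""
        dendropy = pytest.importorskip("dendropy")
        import io as _io
        from indelpop import write_distance_matrix
        buf = _io.StringIO()
        write_distance_matrix(da_fixture, buf, format="csv")
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(buf.getvalue()), delimiter=",")
        ref = pdm.nj_tree()
        ref_splits = set()
        all_taxa = frozenset(t.label for t in ref.taxon_namespace)
        for edge in ref.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf():
                side = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter())
                if 1 < len(side) < len(all_taxa) - 1:
                    ref_splits.add(min(side, all_taxa - side,
                                       key=lambda s: (len(s), sorted(s))))
        ours = neighbor_joining(da_fixture).neighbor_sets()
        assert ours == ref_splits

    def test_branch_lengths_nonnegative(self, da_fixture):
        tree = neighbor_joining(da_fixture)

        def walk(node):
            for child, bl in node.children:
                assert bl >= 0.0
                walk(child)

        walk(tree.root)


class TestNewick:
    def test_round_trip_through_dendropy(self, da_fixture):
        dendropy = pytest.importorskip("dendropy")
        tree = neighbor_joining(da_fixture)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        labels = sorted(l.taxon.label for l in parsed.leaf_node_iter())
        assert labels == sorted(da_fixture.labels)
        # total branch length preserved
        ours = 0.0

        def walk(node):
            nonlocal ours
            for child, bl in node.children:
                ours += bl
                walk(child)

        walk(tree.root)
        assert parsed.length() == pytest.approx(ours, rel=1e-6)

    def test_labels_with_spaces_quoted(self):
        dm = DistanceMatrix(["A A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        nwk = to_newick(neighbor_joining(dm))
        assert "'A A'" in nwk


class TestNearestNeighbor:
    def test_fixture_nearest_and_second(self, da_fixture):
        assert nearest_neighbor(da_fixture, "Xinjiang Uigur") == \
            ("Urumchi Uigur", pytest.approx(0.0012))
        assert nearest_neighbor(da_fixture, "Xinjiang Uigur", rank=2) == \
            ("Kazak", pytest.approx(0.0019))

    def test_two_by_two(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0.0]]))
        assert nearest_neighbor(dm, "A") == ("B", 0.5)

    def test_unknown_label(self, da_fixture):
        with pytest.raises(KeyError):
            nearest_neighbor(da_fixture, "Atlantis")

    def test_tie_broken_by_label_order(self):
        d = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0.0]])
        dm = DistanceMatrix(["X", "B", "A"], d)
        assert nearest_neighbor(dm, "X") == ("A", 1.0)


def small_freq_table(matrix, pops=None):
    matrix = np.asarray(matrix, dtype=float)
    pops = pops or [f"pop{i + 1}" for i in range(matrix.shape[0])]
    return FreqTable(
        populations=pops,
        sample_sizes=[100] * matrix.shape[0],
        loci=[f"L{j + 1}" for j in range(matrix.shape[1])],
        freqs=[[AlleleFrequency.of_ins(v) for v in row] for row in matrix],
    )


class TestPca:
    def test_duplicate_rows_identical_scores(self):
        ft = small_freq_table([[0.2, 0.8, 0.5], [0.2, 0.8, 0.5],
                               [0.6, 0.1, 0.9]])
        res = pca(ft)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-12)

    def test_two_populations_single_axis(self):
        ft = small_freq_table([[0.2, 0.8], [0.6, 0.4]])
        res = pca(ft)
        assert res.explained[0] == pytest.approx(1.0)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            pca(small_freq_table([[0.5, 0.5]]))

    def test_matches_eigendecomposition_oracle(self):
        """Scores/ratios equal an independent covariance eigendecomposition."""
        rng = np.random.default_rng(99)
        x = rng.uniform(0.05, 0.95, size=(10, 30))
        ft = small_freq_table(x)
        res = pca(ft)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(res.explained[:9],
                                   (evals / evals.sum())[:9], atol=1e-8)
        # scores match up to component sign
        oracle_scores = xc @ evecs
        for c in range(9):
            diff = np.abs(res.scores[:, c]) - np.abs(oracle_scores[:, c])
            np.testing.assert_allclose(diff, 0, atol=1e-8)

    def test_variance_conserved(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(8, 12))
        ft = small_freq_table(x)
        res = pca(ft)
        total_centered = ((x - x.mean(axis=0)) ** 2).sum()
        assert (res.scores ** 2).sum() == pytest.approx(total_centered,
                                                        rel=1e-9)
        assert np.all(np.diff(res.explained) <= 1e-12)
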