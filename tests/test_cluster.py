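"""Distances, hierarchical clustering, neighbor joining, silhouettes."""

import numpy as np
import pytest

import specsel as ss
from specsel.cluster import (DistanceMatrix, euclidean_distance,
                             hierarchical_cluster, nj_tree, pearson_distance,
                             silhouette_from_data, silhouette_from_tree,
                             tree_distances)


def random_additive_case(n_taxa, rng):
    """Random unrooted binary tree with uniform branch lengths; returns
    its exact leaf-to-leaf path-length matrix (an additive distance)."""
    leaves = [f"L{i}" for i in range(n_taxa)]
    # adjacency with weights, built by random sequential joins
    adj = {v: {} for v in leaves}
    active = leaves[:]
    counter = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[int(j)], active[int(i)]
        new = f"I{counter}"
        counter += 1
        adj[new] = {}
        for x in (a, b):
            w = float(rng.uniform(0.1, 2.0))
            adj[x][new] = w
            adj[new][x] = w
        active = [x for x in active if x not in (a, b)] + [new]
    w = float(rng.uniform(0.1, 2.0))
    a, b = active
    adj[a][b] = w
    adj[b][a] = w

    def path_len(src, dst):
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, wt in adj[node].items():
                if nxt != prev:
                    stack.append((nxt, node, acc + wt))
        raise AssertionError("disconnected tree")

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = path_len(leaves[i], leaves[j])
    return DistanceMatrix(tuple(leaves), d)


def reordered(dm: DistanceMatrix, ids) -> np.ndarray:
    idx = [dm.ids.index(i) for i in ids]
    return dm.values[np.ix_(idx, idx)]


class TestPearsonDistance:
    def test_self_distance_zero(self):
        X = np.array([[1.0, 2, 3], [1, 2, 3]])
        d = pearson_distance(X)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_negation_distance_two(self):
        d = pearson_distance(np.array([[1.0, 2, 3], [-1, -2, -3]]))
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_perfect_scaling_distance_zero(self):
        d = pearson_distance(np.array([[1.0, 2, 3], [2, 4, 6]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_constant_vector_distance_one(self):
        d = pearson_distance(np.array([[1.0, 2, 3], [5, 5, 5]]))
        assert d.values[0, 1] == 1.0
        assert d.values[1, 1] == 0.0


class TestHierarchical:
    def test_hand_agglomeration_three_points(self):
        d = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.]]))
        Z, order = hierarchical_cluster(d, linkage="average")
        assert Z[0, 2] == pytest.approx(1.0)    # (A,B) merge height
        assert Z[1, 2] == pytest.approx(10.0)   # C joins at 10
        assert set(order) == {"A", "B", "C"}

    def test_two_tight_groups_first_cut(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(8, 0.1, (4, 3))])
        ids = tuple("ABCDEFGH")
        d = euclidean_distance(X, ids)
        _, order = hierarchical_cluster(d)
        halves = {frozenset(order[:4]), frozenset(order[4:])}
        assert halves == {frozenset("ABCD"), frozenset("EFGH")}

    def test_merge_heights_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        ids = tuple("ABCDEF")
        d1 = euclidean_distance(X, ids)
        perm = [3, 1, 5, 0, 2, 4]
        d2 = euclidean_distance(X[perm], tuple(ids[i] for i in perm))
        Z1, _ = hierarchical_cluster(d1)
        Z2, _ = hierarchical_cluster(d2)
        assert np.allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))


class TestNJTree:
    def test_known_four_taxon_tree_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        d = DistanceMatrix(("A", "B", "C", "D"), np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0.],
        ]))
        t = nj_tree(d)
        td = tree_distances(t)
        assert np.allclose(reordered(td, d.ids), d.values, atol=1e-12)
        # A and B must be siblings
        tips = {x.name for x in t.find("A").parent.children if x.is_tip()}
        assert tips == {"A", "B"}

    def test_equidistant_three_points_star(self):
        d = DistanceMatrix(("A", "B", "C"),
                           np.full((3, 3), 2.0) - 2 * np.eye(3))
        t = nj_tree(d)
        assert sorted(c.length for c in t.children) == [1.0, 1.0, 1.0]

    def test_two_samples_single_edge(self):
        d = DistanceMatrix(("A", "B"), np.array([[0, 4.0], [4.0, 0]]))
        t = nj_tree(d)
        assert tree_distances(t).values[0, 1] == pytest.approx(4.0)

    def test_additivity_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            dm = random_additive_case(6, rng)
            td = tree_distances(nj_tree(dm))
            assert np.allclose(reordered(td, dm.ids), dm.values, atol=1e-9)

    def test_matches_reference_nj_on_additive_input(self):
        """Cross-check against the scikit-bio NJ implementation."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        rng = np.random.default_rng(9)
        for _ in range(5):
            dm = random_additive_case(7, rng)
            ours = tree_distances(nj_tree(dm))
            ref = sknj(SkDM(dm.values, ids=list(dm.ids))).tip_tip_distances()
            ref_ids = tuple(str(i) for i in ref.ids)
            ref_dm = DistanceMatrix(ref_ids, np.asarray(ref.data, dtype=float))
            assert np.allclose(reordered(ours, dm.ids),
                               reordered(ref_dm, dm.ids), atol=1e-8)

    def test_invariant_to_taxon_order(self):
        rng = np.random.default_rng(11)
        dm = random_additive_case(6, rng)
        perm = [4, 2, 0, 5, 1, 3]
        ids_p = tuple(dm.ids[i] for i in perm)
        dm_p = DistanceMatrix(ids_p, dm.values[np.ix_(perm, perm)])
        t1 = tree_distances(nj_tree(dm))
        t2 = tree_distances(nj_tree(dm_p))
        assert np.allclose(reordered(t1, dm.ids), reordered(t2, dm.ids),
                           atol=1e-12)


class TestSilhouette:
    def test_tight_separated_clusters_near_one(self):
        eps = 0.01
        d = np.array([
            [0, eps, 1 / eps, 1 / eps],
            [eps, 0, 1 / eps, 1 / eps],
            [1 / eps, 1 / eps, 0, eps],
            [1 / eps, 1 / eps, eps, 0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        _, sc = silhouette_from_data(dm, np.array(["X", "X", "Y", "Y"]))
        assert sc > 0.99

    def test_swapped_labels_negative(self):
        eps = 0.01
        d = np.array([
            [0, eps, 1 / eps, 1 / eps],
            [eps, 0, 1 / eps, 1 / eps],
            [1 / eps, 1 / eps, 0, eps],
            [1 / eps, 1 / eps, eps, 0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        _, sc = silhouette_from_data(dm, np.array(["X", "Y", "X", "Y"]))
        assert sc < 0

    def test_hand_distance_matrix_formula(self):
        d = np.array([
            [0, 1, 4, 5],
            [1, 0, 3, 4],
            [4, 3, 0, 2],
            [5, 4, 2, 0.],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        s, sc = silhouette_from_data(dm, np.array(["X", "X", "Y", "Y"]))
        # direct per-sample evaluation
        expect_a = (np.mean([4, 5]) - 1) / max(1, np.mean([4, 5]))
        expect_c = (np.mean([4, 3]) - 2) / max(2, np.mean([4, 3]))
        assert s["a"] == pytest.approx(expect_a)
        assert s["c"] == pytest.approx(expect_c)
        assert np.all(np.abs(s.values) <= 1.0)
        assert sc == pytest.approx(s.mean())

    def test_tree_silhouette_equals_data_silhouette_for_additive(self):
        rng = np.random.default_rng(3)
        dm = random_additive_case(6, rng)
        labels = {i: ("X" if k < 3 else "Y") for k, i in enumerate(dm.ids)}
        _, sc_data = silhouette_from_data(dm, labels)
        sc_tree = silhouette_from_tree(nj_tree(dm), labels)
        assert sc_tree == pytest.approx(sc_data, abs=1e-9)

    def test_tree_silhouette_is_silhouette_of_path_distances(self):
        rng = np.random.default_rng(5)
        dm = random_additive_case(7, rng)
        # perturb to a non-additive matrix; the composition must still hold
        noisy = dm.values + rng.uniform(0, 0.2, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm2 = DistanceMatrix(dm.ids, noisy)
        t = nj_tree(dm2)
        labels = {i: ("X" if k % 2 else "Y") for k, i in enumerate(dm.ids)}
        _, sc_direct = silhouette_from_data(tree_distances(t), labels)
        assert silhouette_from_tree(t, labels) == pytest.approx(sc_direct)

    def test_selection_improves_silhouette_on_planted_data(self, planted_small):
        m, ann, truth = planted_small
        f = ss.filter_low_counts(m)
        labels = ann.labels_for(f.run_ids)
        _, sc_all = silhouette_from_data(ss.cluster.sample_distances(f), labels)
        kept = [p for p in truth.protein_id if p in f.protein_ids]
        sub = f.subset_proteins(kept)
        _, sc_sel = silhouette_from_data(ss.cluster.sample_distances(sub), labels)
        assert sc_sel >= sc_all
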