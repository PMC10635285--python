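"""Laplacian construction, filtrations, and Betti-0 against oracles."""

import numpy as np
import pytest

from topopca import (
    accumulate,
    betti0,
    distance_filtration,
    gaussian_adjacency,
    knn_filtration,
    knn_index,
    reciprocal_zeta,
    toy_geometries,
)


def union_find_components(n: int, edges) -> int:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(n)})


def assert_laplacian_contract(L, rtol=1e-8):
    assert np.array_equal(L, L.T)
    assert np.max(np.abs(L.sum(axis=1))) < 1e-10
    eig = np.linalg.eigvalsh(L)
    assert eig[0] > -rtol * max(1.0, eig[-1])


class TestKnnIndex:
    def test_line4_neighbor_sets(self):
        # brute force on {0,1,3,7}: 0->1, 1->0, 3->1, 7->3
        nbrs = knn_index(toy_geometries("line4"), k=1)
        assert nbrs == [[1], [0], [1], [2]]

    def test_full_k_gives_complete_union(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        nbrs = knn_index(pts, k=5)
        for i, ns in enumerate(nbrs):
            assert sorted(ns + [i]) == list(range(6))

    def test_coincident_points_tie_break_by_index(self):
        pts = np.array([[0.0], [0.0], [5.0]])
        nbrs = knn_index(pts, k=1)
        assert nbrs[0] == [1] and nbrs[1] == [0]
        assert nbrs[2] == [0]  # tie between the two coincident points -> index 0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            knn_index(np.zeros((3, 1)), k=3)


class TestGaussianAdjacency:
    def test_kernel_values(self):
        pts = np.array([[0.0], [1.0], [1.0]])
        g = gaussian_adjacency(pts, k=2, eta=1.0)
        assert g.W[0, 1] == pytest.approx(np.exp(-1))  # squared distance = eta
        assert g.W[1, 2] == pytest.approx(1.0)  # coincident neighbors
        assert np.all(np.diag(g.W) == 0)

    def test_non_neighbor_pairs_zero(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        g = gaussian_adjacency(pts, k=1, eta=1.0)
        assert g.W[0, 2] == 0.0 and g.W[0, 3] == 0.0

    def test_laplacian_contract_and_auto_eta(self, rng):
        pts = rng.normal(size=(30, 4))
        g = gaussian_adjacency(pts, k=5, eta="auto")
        assert g.eta > 0
        assert_laplacian_contract(g.L)
        assert np.all(g.W >= 0) and np.all(g.W <= 1)

    def test_bad_eta_rejected(self, rng):
        with pytest.raises(ValueError):
            gaussian_adjacency(rng.normal(size=(5, 2)), k=2, eta=-1.0)


class TestDistanceFiltration:
    def test_three_weights_edge_counts(self):
        # supported l-values {-0.9,-0.5,-0.2}; thresholds at p=3 give 1,2,3 edges
        filt = distance_filtration(toy_geometries("three_weights"), p=3)
        assert [len(e) for e in filt.edge_sets()] == [1, 2, 3]
        assert filt.edge_sets()[0] == {(0, 1)}

    def test_last_step_has_all_supported_edges(self, rng):
        pts = rng.normal(size=(25, 3))
        g = gaussian_adjacency(pts, k=4)
        filt = distance_filtration(g, p=5)
        support = set(zip(*np.nonzero(np.triu(g.W, 1) > 0)))
        assert filt.edge_sets()[-1] == support

    def test_p1_equals_unweighted_knn_laplacian(self, rng):
        pts = rng.normal(size=(15, 2))
        g = gaussian_adjacency(pts, k=3)
        filt = distance_filtration(g, p=1)
        expected = np.where(g.W > 0, -1.0, 0.0)
        np.fill_diagonal(expected, 0)
        np.fill_diagonal(expected, -expected.sum(axis=1))
        np.testing.assert_array_equal(filt.laplacians[0], expected)

    def test_equal_weights_degenerate(self):
        from topopca import graph_from_weights

        W = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        filt = distance_filtration(graph_from_weights(W), p=4)
        for L in filt.laplacians:
            assert np.sum(np.triu(L, 1) != 0) == 3

    def test_inverted_orientation_is_decreasing(self):
        filt = distance_filtration(
            toy_geometries("three_weights"), p=3, inverted=True
        )
        counts = [len(e) for e in filt.edge_sets()]
        assert counts == sorted(counts, reverse=True)


class TestKnnFiltration:
    def test_line4_first_step(self):
        filt = knn_filtration(toy_geometries("line4"), p=1)
        assert filt.edge_sets()[0] == {(0, 1), (1, 2), (2, 3)}
        np.testing.assert_array_equal(
            np.diag(filt.laplacians[0]), [1, 2, 2, 1]
        )

    def test_last_step_complete_at_p_nminus1(self, rng):
        pts = rng.normal(size=(8, 2))
        filt = knn_filtration(pts, p=7)
        L = filt.laplacians[-1]
        assert np.all(np.diag(L) == 7)
        assert np.all(L[~np.eye(8, dtype=bool)] == -1)

    def test_matches_gaussian_support_at_same_k(self, rng):
        pts = rng.normal(size=(20, 3))
        k = 4
        filt = knn_filtration(pts, p=k)
        g = gaussian_adjacency(pts, k=k)
        expected = np.where(g.W > 0, -1.0, 0.0)
        np.fill_diagonal(expected, 0)
        np.fill_diagonal(expected, -expected.sum(axis=1))
        np.testing.assert_array_equal(filt.laplacians[-1], expected)

    def test_p_out_of_range(self, rng):
        with pytest.raises(ValueError):
            knn_filtration(rng.normal(size=(5, 2)), p=5)


class TestNestednessAndContracts:
    @pytest.mark.parametrize("mode", ["distance", "knn"])
    def test_nested_and_psd_on_random_clouds(self, mode):
        rng = np.random.default_rng(99)
        for trial in range(25):
            n = int(rng.integers(6, 61))
            pts = rng.normal(size=(n, int(rng.integers(1, 5))))
            if mode == "knn":
                filt = knn_filtration(pts, p=min(5, n - 1))
            else:
                g = gaussian_adjacency(pts, k=min(4, n - 1))
                filt = distance_filtration(g, p=5)
                assert_laplacian_contract(g.L)
            edge_sets = filt.edge_sets()
            b_prev = None
            for L, edges in zip(filt.laplacians, edge_sets):
                assert_laplacian_contract(L)
                b = betti0(L)
                assert b == union_find_components(n, edges)
                if b_prev is not None:
                    assert b <= b_prev
                b_prev = b
            for e1, e2 in zip(edge_sets, edge_sets[1:]):
                assert e1 <= e2


class TestAccumulate:
    def test_one_hot_returns_single_step(self, rng):
        filt = knn_filtration(rng.normal(size=(10, 2)), p=3)
        z = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(accumulate(filt, z).PL, filt.laplacians[1])

    def test_reciprocal_weights(self, rng):
        filt = knn_filtration(rng.normal(size=(10, 2)), p=2)
        acc = accumulate(filt, reciprocal_zeta(2))
        np.testing.assert_allclose(
            acc.PL, filt.laplacians[0] + 0.5 * filt.laplacians[1]
        )
        assert_laplacian_contract(acc.PL)

    def test_zero_zeta_warns_and_zeroes(self, rng):
        filt = knn_filtration(rng.normal(size=(6, 2)), p=2)
        with pytest.warns(UserWarning):
            acc = accumulate(filt, np.zeros(2))
        assert np.all(acc.PL == 0)

    def test_bad_zeta_rejected(self, rng):
        filt = knn_filtration(rng.normal(size=(6, 2)), p=2)
        with pytest.raises(ValueError):
            accumulate(filt, np.ones(3))
        with pytest.raises(ValueError):
            accumulate(filt, np.array([1.0, -0.5]))


class TestBetti0:
    def test_two_blocks_fixture(self):
        assert betti0(toy_geometries("two_blocks")) == 2

    def test_complete_graph_connected(self):
        n = 6
        L = n * np.eye(n) - np.ones((n, n))
        assert betti0(L) == 1

    def test_zero_matrix_all_isolated(self):
        assert betti0(np.zeros((7, 7))) == 7

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            betti0(np.array([[1.0, -1.0], [0.0, 1.0]]))

    def test_agrees_with_union_find_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            density = rng.random() * 0.2
            A = rng.random((n, n)) < density
            A = np.triu(A, 1)
            edges = list(zip(*np.nonzero(A)))
            Adj = (A | A.T).astype(float)
            L = np.diag(Adj.sum(axis=1)) - Adj
            assert betti0(L) == union_find_components(n, edges)
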