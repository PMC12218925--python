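import numpy as np
import pytest
from sklearn.neighbors import NearestNeighbors

from cytohgnn import (
    Hypergraph,
    build_hypergraph,
    euclidean_distance,
    hypergraph_convolve,
    k_nearest,
    propagation_operator,
    toy_fixture,
)
from cytohgnn.exceptions import DegenerateInputError, ShapeError
from cytohgnn.hypergraph import load_hypergraph, save_hypergraph


def brute_force_operator(hg):
    """Triple-loop oracle for P = Dv^-1/2 H W De^-1 H^T Dv^-1/2."""
    H = hg.H.toarray()
    Dv, De, W = hg.Dv, hg.De, hg.W
    n, m = H.shape
    P = np.zeros((n, n))
    for v in range(n):
        for u in range(n):
            for e in range(m):
                P[v, u] += H[v, e] * W[e] * H[u, e] / (De[e] * np.sqrt(Dv[v] * Dv[u]))
    return P


def brute_force_knn(X, i, k):
    """Sort all other vertices by (distance, index) and take the first k."""
    d = [(euclidean_distance(X[i], X[j]), j) for j in range(len(X)) if j != i]
    return [j for _, j in sorted(d)[:k]]


class TestEuclideanDistance:
    def test_identity_of_indiscernibles(self, rng):
        p = rng.normal(size=8)
        assert euclidean_distance(p, p) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            p, q = rng.normal(size=(2, 6))
            assert euclidean_distance(p, q) == euclidean_distance(q, p)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKNearest:
    def test_four_point_instance(self):
        fx = toy_fixture()
        assert list(k_nearest(0, fx.points, 1)) == [1]
        assert list(k_nearest(2, fx.points, 1)) == [3]

    def test_k_equals_n_minus_one_is_exhaustive(self, rng):
        X = rng.normal(size=(7, 3))
        assert sorted(k_nearest(2, X, 6)) == [0, 1, 3, 4, 5, 6]

    def test_ties_broken_by_lowest_index(self):
        # vertices 1, 2, 3 are duplicates, all at distance sqrt(2) from 0
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert list(k_nearest(0, X, 2)) == [1, 2]

    def test_matches_brute_force_and_sklearn(self, rng):
        X = rng.normal(size=(25, 4))
        nn = NearestNeighbors(n_neighbors=6).fit(X)
        _, sk_idx = nn.kneighbors(X)
        for i in range(25):
            ours = list(k_nearest(i, X, 5))
            assert ours == brute_force_knn(X, i, 5)
            assert sorted(ours) == sorted(sk_idx[i, 1:].tolist())

    def test_k_out_of_range(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(DegenerateInputError):
            k_nearest(0, X, 5)


class TestBuildHypergraph:
    def test_four_point_worked_instance(self):
        fx = toy_fixture()
        hg = build_hypergraph(fx.points, fx.k)
        np.testing.assert_array_equal(hg.H.toarray(), fx.expected_H)
        np.testing.assert_array_equal(hg.Dv, fx.expected_Dv)
        np.testing.assert_array_equal(hg.De, fx.expected_De)
        np.testing.assert_array_equal(hg.W, 1.0)

    def test_complete_hyperedges_at_k_max(self, rng):
        X = rng.normal(size=(6, 3))
        hg = build_hypergraph(X, 5)
        np.testing.assert_array_equal(hg.H.toarray(), np.ones((6, 6)))

    def test_self_only_hyperedges_at_k_zero(self, rng):
        X = rng.normal(size=(6, 3))
        hg = build_hypergraph(X, 0)
        np.testing.assert_array_equal(hg.H.toarray(), np.eye(6))
        np.testing.assert_array_equal(hg.Dv, 1.0)
        np.testing.assert_array_equal(hg.De, 1.0)

    def test_column_sums_equal_k_plus_one(self, rng):
        for k in (1, 3, 7):
            X = rng.normal(size=(15, 5))
            hg = build_hypergraph(X, k)
            np.testing.assert_array_equal(
                np.asarray(hg.H.sum(axis=0)).ravel(), k + 1
            )

    def test_degrees_match_defining_sums(self, rng):
        X = rng.normal(size=(12, 3))
        hg = build_hypergraph(X, 4)
        H = hg.H.toarray()
        np.testing.assert_array_equal(hg.Dv, H @ hg.W)
        np.testing.assert_array_equal(hg.De, H.sum(axis=0))

    def test_nan_features_rejected(self):
        X = np.array([[0.0, 1.0], [np.nan, 0.0], [1.0, 1.0]])
        with pytest.raises(ShapeError):
            build_hypergraph(X, 1)

    def test_edge_list_round_trip(self, rng, tmp_path):
        hg = build_hypergraph(rng.normal(size=(10, 3)), 3)
        path = tmp_path / "hg.edges"
        save_hypergraph(hg, path)
        loaded = load_hypergraph(path)
        np.testing.assert_array_equal(hg.H.toarray(), loaded.H.toarray())
        np.testing.assert_array_equal(hg.W, loaded.W)
        assert loaded.k == hg.k


class TestPropagationOperator:
    def test_identity_at_k_zero(self, rng):
        hg = build_hypergraph(rng.normal(size=(8, 3)), 0)
        np.testing.assert_array_equal(propagation_operator(hg).dense(), np.eye(8))

    def test_single_full_hyperedge_averages(self):
        """One hyperedge over all N vertices: P = (1/N) * ones."""
        n = 6
        hg = Hypergraph(H=np.ones((n, 1)), W=np.ones(1), k=n - 1)
        P = propagation_operator(hg).dense()
        np.testing.assert_allclose(P, np.full((n, n), 1.0 / n), atol=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        """Entrywise agreement with the (v, e, u) triple-loop oracle."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 21))
            k = int(rng.integers(1, min(6, n)))
            hg = build_hypergraph(rng.normal(size=(n, 3)), k)
            P = propagation_operator(hg).dense()
            np.testing.assert_allclose(P, brute_force_operator(hg), atol=1e-10)

    def test_operator_invariants(self, rng):
        """Symmetry, non-negativity, degree-vector fixed point, spectrum."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            hg = build_hypergraph(r.normal(size=(20, 4)), 5)
            P = propagation_operator(hg).dense()
            assert np.abs(P - P.T).max() < 1e-10
            assert P.min() >= 0
            z = np.sqrt(hg.Dv)
            assert np.abs(P @ z - z).max() < 1e-8
            eigs = np.linalg.eigvalsh(P)
            assert eigs.min() >= -1 - 1e-8 and eigs.max() <= 1 + 1e-8

    def test_isolated_vertex_rejected(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        hg = Hypergraph(H=H, W=np.ones(2), k=0)
        with pytest.raises(DegenerateInputError):
            propagation_operator(hg)


class TestHypergraphConvolve:
    def test_identity_propagation(self, rng):
        X = rng.normal(size=(6, 4))
        hg = build_hypergraph(X, 0)
        out = hypergraph_convolve(hg, X, np.eye(4), activation=None)
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_full_hyperedge_gives_column_means(self, rng):
        n = 5
        hg = Hypergraph(H=np.ones((n, 1)), W=np.ones(1), k=n - 1)
        X = rng.normal(size=(n, 3))
        out = hypergraph_convolve(hg, X, np.eye(3), activation=None)
        np.testing.assert_allclose(out, np.tile(X.mean(axis=0), (n, 1)), atol=1e-12)

    def test_matches_per_vertex_brute_force(self):
        """sigma(P X Theta) equals explicit per-vertex aggregation."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 16))
            hg = build_hypergraph(rng.normal(size=(n, 3)), 2)
            X = rng.normal(size=(n, 4))
            Theta = rng.normal(size=(4, 2))
            out = hypergraph_convolve(hg, X, Theta, activation=None)
            expected = brute_force_operator(hg) @ X @ Theta
            np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_relabeling_equivariance(self, rng):
        """Permuting vertices and permuting back leaves P X invariant."""
        X = rng.normal(size=(12, 3))
        k = 3
        perm = rng.permutation(12)
        P = propagation_operator(build_hypergraph(X, k)).dense()
        P_perm = propagation_operator(build_hypergraph(X[perm], k)).dense()
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            (P_perm @ X[perm])[inv], P @ X, atol=1e-10
        )

    def test_shape_mismatch_rejected(self, rng):
        hg = build_hypergraph(rng.normal(size=(6, 3)), 2)
        with pytest.raises(ShapeError):
            hypergraph_convolve(hg, rng.normal(size=(6, 4)), rng.normal(size=(3, 2)))
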