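import itertools

import numpy as np
import pytest

from grnmf_mda import (
    ClusterSet,
    SimilarityMatrix,
    build_regularized_graph,
    cluster_one,
    masked_graph,
    neighbor_weight_matrix,
)
from grnmf_mda.graph import read_cluster_file


def simmat(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"v{i:02d}" for i in range(values.shape[0])]
    return SimilarityMatrix(values, labels)


def block_similarity(sizes, within=1.0, between=0.0, rng=None):
    n = sum(sizes)
    S = np.full((n, n), between)
    start = 0
    blocks = []
    for sz in sizes:
        S[start:start + sz, start:start + sz] = within
        blocks.append(set(range(start, start + sz)))
        start += sz
    if rng is not None:
        noise = rng.uniform(0, 0.02, (n, n))
        S = np.clip(S + (noise + noise.T) / 2, 0, 1)
    np.fill_diagonal(S, 1.0)
    return S, blocks


def cohesiveness(A, members):
    inside = sorted(members)
    w_in = A[np.ix_(inside, inside)].sum() / 2
    w_bound = A[inside].sum() - 2 * w_in
    return w_in / (w_in + w_bound) if w_in + w_bound > 0 else 0.0


class TestClusterOne:
    def test_two_disconnected_cliques_recovered(self):
        S, blocks = block_similarity([4, 3])
        cs = cluster_one(simmat(S))
        labels = simmat(S).labels
        got = {frozenset(labels.index(x) for x in cl) for cl in cs.clusters}
        assert got == {frozenset(b) for b in blocks}

    def test_identity_similarity_gives_singletons(self):
        cs = cluster_one(simmat(np.eye(5)))
        assert sorted(len(c) for c in cs.clusters) == [1] * 5
        assert len({x for c in cs.clusters for x in c}) == 5

    def test_planted_two_blocks_beat_all_bipartitions(self):
        # exhaustive oracle: among all 2-partitions of 12 nodes the planted
        # blocks maximize summed cohesiveness; cluster_one must find them
        rng = np.random.default_rng(0)
        S = np.full((12, 12), 0.05)
        S[:6, :6] = 0.9
        S[6:, 6:] = 0.9
        jitter = rng.uniform(0, 0.02, (12, 12))
        S = np.clip(S + (jitter + jitter.T) / 2, 0, 1)
        np.fill_diagonal(S, 1.0)
        A = S.copy()
        np.fill_diagonal(A, 0.0)
        best, best_val = None, -1.0
        universe = set(range(12))
        for r in range(1, 6 + 1):
            for part in itertools.combinations(range(12), r):
                a = set(part)
                val = cohesiveness(A, a) + cohesiveness(A, universe - a)
                if val > best_val:
                    best_val, best = val, {frozenset(a), frozenset(universe - a)}
        assert best == {frozenset(range(6)), frozenset(range(6, 12))}
        sm = simmat(S)
        got = {frozenset(sm.labels.index(x) for x in cl)
               for cl in cluster_one(sm).clusters}
        assert got == best

    def test_external_cluster_file(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("a\tb\nc\n")
        cs = read_cluster_file(f, ["a", "b", "c"])
        assert cs.clusters == [frozenset({"a", "b"}), frozenset({"c"})]
        with pytest.raises(ValueError, match="unknown"):
            read_cluster_file(f, ["a", "b"])


class TestNeighborWeightMatrix:
    def setup_method(self):
        # v0-v1 mutually nearest and co-clustered; v2 similar to v0 only
        # one-directionally; v3 isolated
        S = np.array([
            [1.0, 0.9, 0.4, 0.0],
            [0.9, 1.0, 0.3, 0.0],
            [0.4, 0.3, 1.0, 0.1],
            [0.0, 0.0, 0.1, 1.0],
        ])
        self.S = simmat(S, ["a", "b", "c", "d"])

    def test_three_branches(self):
        clusters = ClusterSet([frozenset({"a", "b"}), frozenset({"c"}), frozenset({"d"})])
        X = neighbor_weight_matrix(self.S, clusters, p=1)
        assert X[0, 1] == 1.0  # mutual 1-NN, shared cluster
        assert X[0, 3] == 0.0  # neither neighbors nor co-clustered
        # a is c's 1-NN but not vice versa, no shared cluster -> mixed
        assert X[0, 2] == 0.5
        assert np.array_equal(np.diag(X), np.ones(4))

    def test_symmetric_for_any_input(self, rng):
        n = 9
        V = rng.random((n, n))
        V = np.clip((V + V.T) / 2, 0, 1)
        np.fill_diagonal(V, 1.0)
        S = simmat(V)
        clusters = cluster_one(S, density_threshold=0.3)
        X = neighbor_weight_matrix(S, clusters, p=3)
        assert np.array_equal(X, X.T)
        assert set(np.unique(X)) <= {0.0, 0.5, 1.0}

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            neighbor_weight_matrix(self.S, ClusterSet([]), p=4)


class TestMaskedGraph:
    def test_identity_mask_keeps_similarity(self, rng):
        V = rng.random((5, 5))
        V = np.clip((V + V.T) / 2, 0, 1)
        np.fill_diagonal(V, 1.0)
        S = simmat(V)
        G = masked_graph(S, np.ones((5, 5)))
        assert np.array_equal(G.weights, V)
        assert np.abs(G.laplacian.sum(axis=1)).max() < 1e-12

    def test_hand_laplacian(self):
        S = simmat([[1.0, 0.5], [0.5, 1.0]], ["a", "b"])
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = masked_graph(S, X)
        assert np.array_equal(G.weights, [[0.0, 0.5], [0.5, 0.0]])
        assert np.array_equal(G.degree, np.diag([0.5, 0.5]))
        assert np.array_equal(G.laplacian, [[0.5, -0.5], [-0.5, 0.5]])

    def test_quadratic_form_identity_and_psd(self, rng):
        V = rng.random((6, 6))
        V = np.clip((V + V.T) / 2, 0, 1)
        np.fill_diagonal(V, 1.0)
        S = simmat(V)
        clusters = cluster_one(S, density_threshold=0.2)
        X = neighbor_weight_matrix(S, clusters, p=2)
        G = masked_graph(S, X)
        for _ in range(100):
            x = rng.normal(size=6)
            quad = x @ G.laplacian @ x
            direct = 0.5 * sum(
                G.weights[i, j] * (x[i] - x[j]) ** 2
                for i in range(6) for j in range(6)
            )
            assert quad == pytest.approx(direct, abs=1e-9)
        assert np.linalg.eigvalsh(G.laplacian).min() >= -1e-8

    def test_sparsification_never_adds_edges(self, rng):
        V = rng.random((8, 8))
        V = np.clip((V + V.T) / 2, 0, 1)
        np.fill_diagonal(V, 1.0)
        S = simmat(V)
        G = build_regularized_graph(S, p=2)
        assert np.count_nonzero(G.weights) <= np.count_nonzero(S.values)

    def test_asymmetric_mask_rejected(self):
        S = simmat(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            masked_graph(S, np.array([[1.0, 1.0], [0.0, 1.0]]))
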