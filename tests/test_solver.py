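import numpy as np
import pytest

from grnmf_mda import (
    AdjacencyMatrix,
    FactorPair,
    SimilarityMatrix,
    SolverConfig,
    fit,
    gip_kernel,
    grid_search,
    kkt_residual,
    masked_graph,
    multiplicative_step,
    objective,
    predict_scores,
)

from oracles import objective_loop, predict_loop


def adj(values):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return AdjacencyMatrix(values, [f"m{i:02d}" for i in range(m)],
                           [f"d{j:02d}" for j in range(n)])


def trivial_graph(n, labels=None):
    labels = labels or [f"v{i:02d}" for i in range(n)]
    return masked_graph(SimilarityMatrix(np.eye(n), labels), np.ones((n, n)))


def gip_graphs(Y):
    m, n = Y.shape
    Gm = masked_graph(gip_kernel(Y, "microbe"), np.ones((m, m)))
    Gd = masked_graph(gip_kernel(Y, "disease"), np.ones((n, n)))
    return Gm, Gd


class TestObjective:
    def test_zero_factors_give_squared_frobenius(self, rng):
        Y = adj(rng.random((4, 3)))
        cfg = SolverConfig(rank_k=2, lambda_l=0, lambda_m=0, lambda_d=0)
        W, H = np.zeros((4, 2)), np.zeros((3, 2))
        val = objective(Y, W, H, trivial_graph(4), trivial_graph(3), cfg)
        assert val == pytest.approx((Y.values**2).sum())

    def test_exact_factorization_gives_zero(self, rng):
        W = rng.random((4, 2))
        H = rng.random((3, 2))
        Y = adj(W @ H.T)
        cfg = SolverConfig(rank_k=2, lambda_l=0, lambda_m=0, lambda_d=0)
        assert objective(Y, W, H, trivial_graph(4), trivial_graph(3), cfg) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_loop_evaluation(self, rng):
        Y = adj((rng.random((6, 4)) < 0.4).astype(float))
        Y.values[0, 0] = 1.0
        Gm, Gd = gip_graphs(Y)
        cfg = SolverConfig(rank_k=2, lambda_l=0.3, lambda_m=0.7, lambda_d=0.2)
        W, H = rng.random((6, 2)), rng.random((4, 2))
        got = objective(Y, W, H, Gm, Gd, cfg)
        expected = objective_loop(Y.values, W, H, Gm.laplacian, Gd.laplacian,
                                  0.3, 0.7, 0.2)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_input_rejected(self):
        Y = adj(np.ones((2, 2)))
        cfg = SolverConfig(rank_k=1)
        with pytest.raises(ValueError):
            objective(Y, np.full((2, 1), np.inf), np.ones((2, 1)),
                      trivial_graph(2), trivial_graph(2), cfg)


class TestMultiplicativeStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        W = rng.random((5, 2)) + 0.1
        H = rng.random((4, 2)) + 0.1
        Y = adj(W @ H.T)
        cfg = SolverConfig(rank_k=2, lambda_l=0, lambda_m=0, lambda_d=0)
        Wn, Hn = multiplicative_step(Y, W, H, trivial_graph(5), trivial_graph(4), cfg)
        assert np.abs(Wn - W).max() < 1e-12
        assert np.abs(Hn - H).max() < 1e-12

    def test_zero_entries_stay_zero(self, rng):
        Y = adj((rng.random((5, 4)) < 0.4).astype(float))
        Y.values[0, 0] = 1.0
        Gm, Gd = gip_graphs(Y)
        cfg = SolverConfig(rank_k=2)
        W, H = rng.random((5, 2)), rng.random((4, 2))
        W[1, 0] = 0.0
        H[2, 1] = 0.0
        for _ in range(25):
            W, H = multiplicative_step(Y, W, H, Gm, Gd, cfg)
        assert W[1, 0] == 0.0 and H[2, 1] == 0.0
        assert W.min() >= 0.0 and H.min() >= 0.0

    def test_objective_nonincreasing_on_random_instances(self, rng):
        for trial in range(5):
            Y = adj((rng.random((7, 5)) < 0.4).astype(float))
            Y.values[0, 0] = 1.0
            Gm, Gd = gip_graphs(Y)
            cfg = SolverConfig(rank_k=3, max_iter=150, tol=1e-15, seed=trial)
            fp = fit(Y, Gm, Gd, cfg)
            assert np.diff(fp.objective_trace).max() <= 1e-9


class TestFit:
    def test_huge_tol_stops_after_one_iteration(self, rng):
        Y = adj((rng.random((5, 4)) < 0.5).astype(float))
        Y.values[0, 0] = 1.0
        Gm, Gd = gip_graphs(Y)
        fp = fit(Y, Gm, Gd, SolverConfig(rank_k=2, tol=1e9))
        assert fp.iterations_run == 1 and fp.converged

    def test_same_seed_is_bitwise_identical(self, rng):
        Y = adj((rng.random((6, 4)) < 0.4).astype(float))
        Y.values[0, 0] = 1.0
        Gm, Gd = gip_graphs(Y)
        cfg = SolverConfig(rank_k=2, max_iter=50, seed=42)
        fp1 = fit(Y, Gm, Gd, cfg)
        fp2 = fit(Y, Gm, Gd, cfg)
        assert np.array_equal(fp1.W, fp2.W) and np.array_equal(fp1.H, fp2.H)

    def test_rank_exceeding_dimensions_rejected(self):
        Y = adj(np.eye(3))
        with pytest.raises(ValueError, match="rank_k"):
            fit(Y, trivial_graph(3), trivial_graph(3), SolverConfig(rank_k=4))

    def test_planted_low_rank_matrix_recovered(self, fixture_dataset):
        # fit the rank-4 ground-truth score matrix itself; reconstruction
        # should be accurate despite the regularizers
        _, truth, _ = fixture_dataset
        m, n = truth.shape
        fp = fit(truth, trivial_graph(m, truth.microbe_labels),
                 trivial_graph(n, truth.disease_labels),
                 SolverConfig(rank_k=4, max_iter=2000, tol=1e-10, seed=0))
        rel = np.linalg.norm(truth.values - fp.W @ fp.H.T) / np.linalg.norm(truth.values)
        assert rel < 0.15

    def test_kkt_residual_small_at_convergence(self, rng):
        Y = adj((rng.random((20, 10)) < 0.3).astype(float))
        Y.values[0, 0] = 1.0
        Gm, Gd = gip_graphs(Y)
        cfg = SolverConfig(rank_k=3, max_iter=20000, tol=1e-12, seed=1)
        fp = fit(Y, Gm, Gd, cfg)
        assert kkt_residual(Y, fp.W, fp.H, Gm, Gd, cfg) < 1e-3


class TestPredictScores:
    def test_outer_product(self):
        fp = FactorPair(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]),
                        [0.0], 0, True, ["m1", "m2"], ["d1", "d2"])
        assert predict_scores(fp).values.tolist() == [[3.0, 4.0], [6.0, 8.0]]

    def test_zero_factors_give_zero_scores(self):
        fp = FactorPair(np.zeros((2, 1)), np.zeros((2, 1)), [0.0], 0, True,
                        ["m1", "m2"], ["d1", "d2"])
        assert not predict_scores(fp).values.any()

    def test_matches_double_loop(self, rng):
        W, H = rng.random((6, 3)), rng.random((4, 3))
        fp = FactorPair(W, H, [0.0], 0, True,
                        [f"m{i}" for i in range(6)], [f"d{j}" for j in range(4)])
        assert np.abs(predict_scores(fp).values - predict_loop(W, H)).max() < 1e-10


def test_grid_search_returns_lowest_score(rng):
    Y = adj((rng.random((6, 4)) < 0.5).astype(float))
    Y.values[0, 0] = 1.0
    Gm, Gd = gip_graphs(Y)
    base = SolverConfig(rank_k=2, max_iter=100, seed=0)
    best, results = grid_search(Y, Gm, Gd, base, {"rank_k": [1, 2, 3]})
    assert len(results) == 3
    assert min(s for _, s in results) == \
        [s for p, s in results if p["rank_k"] == best.rank_k][0]
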