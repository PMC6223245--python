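"""Graph-regularized NMF by multiplicative updates.

The preprocessed adjacency matrix Y (m x n) is factorized as Y ~ W H^T with
nonnegative W (m x k) and H (n x k), minimizing

    ||Y - W H^T||_F^2 + lambda_l (||W||_F^2 + ||H||_F^2)
        + lambda_m Tr(W^T L_m W) + lambda_d Tr(H^T L_d H)

where L_m, L_d are the Laplacians of the masked microbe/disease similarity
graphs.  The Tikhonov term smooths the factors; the graph terms pull rows of W
(and of H) together when the corresponding entities are close in the masked
similarity graph.  Minimization uses the classic multiplicative updates
derived from the KKT conditions,

    w_ik <- w_ik (Y H + lambda_m S_m* W)_ik / (W H^T H + lambda_l W + lambda_m D_m W)_ik
    h_jk <- h_jk (Y^T W + lambda_d S_d* H)_jk / (H W^T W + lambda_l H + lambda_d D_d H)_jk

(W updated first, then H with the updated W).  These are
majorization-minimization steps: the objective is non-increasing, factors stay
nonnegative, and exact zeros are locked.  Denominators are floored at ``eps``
rather than smoothing the numerators, which preserves the zero-locking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .data import AdjacencyMatrix
from .graph import RegularizedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "FactorPair",
    "objective",
    "multiplicative_step",
    "fit",
    "predict_scores",
    "kkt_residual",
    "grid_search",
]


@dataclass
class SolverConfig:
    rank_k: int = 10
    lambda_l: float = 0.01
    lambda_m: float = 0.01
    lambda_d: float = 0.01
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.rank_k < 1:
            raise ValueError("rank_k must be >= 1")
        if min(self.lambda_l, self.lambda_m, self.lambda_d) < 0:
            raise ValueError("regularization coefficients must be nonnegative")
        if self.max_iter < 1 or self.tol <= 0 or self.eps <= 0:
            raise ValueError("max_iter >= 1, tol > 0 and eps > 0 required")


@dataclass
class FactorPair:
    """Fitted nonnegative factors with solver diagnostics."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    iterations_run: int
    converged: bool
    microbe_labels: list[str] = field(default_factory=list)
    disease_labels: list[str] = field(default_factory=list)


def objective(
    Y: AdjacencyMatrix,
    W: np.ndarray,
    H: np.ndarray,
    Gm: RegularizedGraph,
    Gd: RegularizedGraph,
    cfg: SolverConfig,
) -> float:
    """Regularized reconstruction objective; nonnegative for PSD Laplacians."""
    if not (np.isfinite(W).all() and np.isfinite(H).all() and np.isfinite(Y.values).all()):
        raise ValueError("non-finite inputs to objective")
    R = Y.values - W @ H.T
    val = float((R * R).sum())
    val += cfg.lambda_l * float((W * W).sum() + (H * H).sum())
    val += cfg.lambda_m * float(np.einsum("ip,ik,pk->", Gm.laplacian, W, W))
    val += cfg.lambda_d * float(np.einsum("jq,jk,qk->", Gd.laplacian, H, H))
    return val


def multiplicative_step(
    Y: AdjacencyMatrix,
    W: np.ndarray,
    H: np.ndarray,
    Gm: RegularizedGraph,
    Gd: RegularizedGraph,
    cfg: SolverConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One sequential multiplicative update: W first, then H with the new W."""
    Yv = Y.values
    dm = Gm.degree_vector
    dd = Gd.degree_vector

    num_w = Yv @ H + cfg.lambda_m * (Gm.weights @ W)
    den_w = W @ (H.T @ H) + cfg.lambda_l * W + cfg.lambda_m * dm[:, None] * W
    W = W * num_w / np.maximum(den_w, cfg.eps)

    num_h = Yv.T @ W + cfg.lambda_d * (Gd.weights @ H)
    den_h = H @ (W.T @ W) + cfg.lambda_l * H + cfg.lambda_d * dd[:, None] * H
    H = H * num_h / np.maximum(den_h, cfg.eps)
    return W, H


def fit(
    Y: AdjacencyMatrix,
    Gm: RegularizedGraph,
    Gd: RegularizedGraph,
    cfg: SolverConfig | None = None,
) -> FactorPair:
    """Run multiplicative updates from a seeded uniform(0,1) initialization.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` iterations; deterministic given the seed.
    """
    cfg = cfg or SolverConfig()
    m, n = Y.shape
    if cfg.rank_k > min(m, n):
        raise ValueError(f"rank_k={cfg.rank_k} exceeds min(m, n)={min(m, n)}")
    rng = np.random.default_rng(cfg.seed)
    W = rng.uniform(size=(m, cfg.rank_k))
    H = rng.uniform(size=(n, cfg.rank_k))
    trace = [objective(Y, W, H, Gm, Gd, cfg)]
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        W, H = multiplicative_step(Y, W, H, Gm, Gd, cfg)
        obj = objective(Y, W, H, Gm, Gd, cfg)
        prev = trace[-1]
        trace.append(obj)
        if abs(obj - prev) / max(prev, cfg.eps) < cfg.tol:
            converged = True
            break
    logger.info(
        "solver: %d iterations, objective %.6g -> %.6g, converged=%s",
        iterations, trace[0], trace[-1], converged,
    )
    return FactorPair(
        W, H, trace, iterations, converged,
        list(Y.microbe_labels), list(Y.disease_labels),
    )


def predict_scores(fp: FactorPair) -> AdjacencyMatrix:
    """Score matrix Y* = W H^T; a higher score means a more likely association."""
    return AdjacencyMatrix(fp.W @ fp.H.T, list(fp.microbe_labels), list(fp.disease_labels))


def kkt_residual(
    Y: AdjacencyMatrix,
    W: np.ndarray,
    H: np.ndarray,
    Gm: RegularizedGraph,
    Gd: RegularizedGraph,
    cfg: SolverConfig,
) -> float:
    """Max-norm of elementwise min(factor, |gradient|) — 0 at a KKT point.

    For a stationary point of the nonnegatively constrained problem either the
    factor entry is 0 or its partial derivative vanishes.
    """
    grad_w = 2.0 * (
        -Y.values @ H + W @ (H.T @ H) + cfg.lambda_l * W + cfg.lambda_m * (Gm.laplacian @ W)
    )
    grad_h = 2.0 * (
        -Y.values.T @ W + H @ (W.T @ W) + cfg.lambda_l * H + cfg.lambda_d * (Gd.laplacian @ H)
    )
    res_w = np.minimum(W, np.abs(grad_w))
    res_h = np.minimum(H, np.abs(grad_h))
    return float(max(np.abs(res_w).max(initial=0.0), np.abs(res_h).max(initial=0.0)))


def grid_search(
    Y: AdjacencyMatrix,
    Gm: RegularizedGraph,
    Gd: RegularizedGraph,
    base_cfg: SolverConfig,
    grid: dict[str, list],
    score_fn: Optional[Callable[[FactorPair], float]] = None,
) -> tuple[SolverConfig, list[tuple[dict, float]]]:
    """Exhaustive hyperparameter sweep; lower ``score_fn`` is better.

    Default score is the final objective value.  Returns the best config and
    the full (params, score) trail.
    """
    if score_fn is None:
        score_fn = lambda fp: fp.objective_trace[-1]
    keys = sorted(grid)
    results: list[tuple[dict, float]] = []
    best: tuple[float, SolverConfig] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = replace(base_cfg, **params)
        score = score_fn(fit(Y, Gm, Gd, cfg))
        results.append((params, score))
        if best is None or score < best[0]:
            best = (score, cfg)
    assert best is not None
    return best[1], results
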