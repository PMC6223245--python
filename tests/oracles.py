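"""Independent reference implementations used only as test oracles.

Everything here is written as literal loops or generic optimization, with no
code shared with the package, so agreement is evidence of correctness rather
than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def gip_loop(Y: np.ndarray, axis: str, gamma_prime: float) -> np.ndarray:
    """Literal Gaussian interaction profile kernel over rows or columns."""
    X = Y if axis == "microbe" else Y.T
    n = X.shape[0]
    total = 0.0
    for i in range(n):
        total += sum(x * x for x in X[i])
    gamma = gamma_prime / (total / n)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((X[i, t] - X[j, t]) ** 2 for t in range(X.shape[1]))
            S[i, j] = np.exp(-gamma * d2)
    return S


def wknn_loop(
    P: np.ndarray,
    sim: np.ndarray,
    labels: list[str],
    K: int,
    alpha: float,
) -> np.ndarray:
    """Literal weighted-KNN profile update over the rows of binary P."""
    n = P.shape[0]
    known = [i for i in range(n) if P[i].sum() > 0]
    out = np.zeros_like(P, dtype=float)
    for q in range(n):
        pool = [i for i in known if i != q]
        if not pool:
            continue
        pool.sort(key=lambda i: (-sim[q, i], labels[i]))
        nbrs = pool[: min(K, len(pool))]
        Q = sum(sim[q, i] for i in nbrs)
        if Q == 0:
            continue
        acc = np.zeros(P.shape[1])
        for rank, i in enumerate(nbrs):
            acc += alpha**rank * sim[q, i] * P[i]
        out[q] = acc / Q
    return np.clip(out, 0.0, 1.0)


def objective_loop(
    Y: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    Lm: np.ndarray,
    Ld: np.ndarray,
    lambda_l: float,
    lambda_m: float,
    lambda_d: float,
) -> float:
    """Term-by-term objective with explicit double loops for the traces."""
    m, n = Y.shape
    val = 0.0
    R = Y - W @ H.T
    for i in range(m):
        for j in range(n):
            val += R[i, j] ** 2
    val += lambda_l * (sum(w * w for w in W.ravel()) + sum(h * h for h in H.ravel()))
    for i in range(m):
        for p in range(m):
            val += lambda_m * Lm[i, p] * float(W[i] @ W[p])
    for j in range(n):
        for q in range(n):
            val += lambda_d * Ld[j, q] * float(H[j] @ H[q])
    return val


def predict_loop(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    m, k = W.shape
    n = H.shape[0]
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            out[i, j] = sum(W[i, t] * H[j, t] for t in range(k))
    return out


def projected_gradient(
    Y: np.ndarray,
    Sm_star: np.ndarray,
    Sd_star: np.ndarray,
    lambda_l: float,
    lambda_m: float,
    lambda_d: float,
    k: int,
    n_iter: int,
    seed: int,
) -> float:
    """Projected gradient descent with Armijo backtracking; returns final objective.

    A generic constrained first-order method sharing nothing with the
    multiplicative-update path except the objective definition.
    """
    Lm = np.diag(Sm_star.sum(axis=1)) - Sm_star
    Ld = np.diag(Sd_star.sum(axis=1)) - Sd_star

    def f(W, H):
        R = Y - W @ H.T
        return (
            float((R * R).sum())
            + lambda_l * float((W * W).sum() + (H * H).sum())
            + lambda_m * float(np.trace(W.T @ Lm @ W))
            + lambda_d * float(np.trace(H.T @ Ld @ H))
        )

    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(Y.shape[0], k))
    H = rng.uniform(size=(Y.shape[1], k))
    step = 1e-2
    fx = f(W, H)
    for _ in range(n_iter):
        gW = 2.0 * (-Y @ H + W @ (H.T @ H) + lambda_l * W + lambda_m * Lm @ W)
        gH = 2.0 * (-Y.T @ W + H @ (W.T @ W) + lambda_l * H + lambda_d * Ld @ H)
        decrease = False
        for _bt in range(40):
            Wn = np.maximum(W - step * gW, 0.0)
            Hn = np.maximum(H - step * gH, 0.0)
            fn = f(Wn, Hn)
            if fn <= fx - 1e-4 * step * (float((gW * gW).sum()) + float((gH * gH).sum())):
                decrease = True
                break
            step *= 0.5
        if not decrease:
            break
        W, H, fx = Wn, Hn, fn
        step *= 2.0
    return fx


def mannwhitney_auc(folds: list[tuple[np.ndarray, float]]) -> float:
    """Per-fold Mann-Whitney U normalization (ties mid-ranked), averaged.

    Each fold is (candidate_scores, test_score).
    """
    us = []
    for cand, s in folds:
        res = mannwhitneyu([s], cand, alternative="two-sided", method="asymptotic")
        us.append(res.statistic / len(cand))
    return float(np.mean(us))
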