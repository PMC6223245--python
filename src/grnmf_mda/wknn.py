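"""Weighted K-nearest-neighbor interaction-profile preprocessing.

Entities (microbes or diseases) with few or no known associations have nearly
empty interaction profiles, which drags factorization scores toward zero.  The
preprocessing step replaces each entity's profile zeros with a likelihood
score borrowed from its K most similar "known" neighbors — entities holding at
least one known association — combined with geometric decay weights:

    new_profile(q) = (1/Q) * sum_{i=1..K} alpha^(i-1) * S(i, q) * profile(i)

with neighbors sorted by descending similarity and Q the plain sum of the K
neighbor similarities.  Note the decay enters the weights but not the
normalizer — that asymmetry is deliberate (it damps lower-ranked neighbors
below a convex average) and matches the antecedent WKNN formulation; a config
flag offers the fully normalized alternative.  Microbe-side and disease-side
profiles are averaged and the original matrix is updated by an elementwise
max, so known associations are never downgraded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import AdjacencyMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["WknnConfig", "wknn_profiles", "combine_and_update", "preprocess"]


@dataclass
class WknnConfig:
    """Neighbor count K, decay alpha in [0,1], combination weights a1/a2."""

    K: int = 5
    alpha: float = 0.9
    a1: float = 1.0
    a2: float = 1.0
    normalize_with_decay: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 <= 0:
            raise ValueError("need a1, a2 >= 0 and a1 + a2 > 0")


def wknn_profiles(
    Y: AdjacencyMatrix,
    S: SimilarityMatrix,
    axis: str = "microbe",
    cfg: WknnConfig | None = None,
) -> AdjacencyMatrix:
    """Compute new interaction profiles along one axis of the binary matrix Y.

    For each entity q the K most similar known entities (>=1 association in the
    original Y, q itself excluded) are selected — similarity ties break by
    label — and their binary profiles are combined with decay weights.  If all
    selected similarities are zero the new profile is all zeros.
    """
    cfg = cfg or WknnConfig()
    if axis not in ("microbe", "disease"):
        raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")
    if not Y.is_binary():
        raise ValueError("WKNN preprocessing expects a binary adjacency matrix")
    P = Y.values if axis == "microbe" else Y.values.T
    labels = Y.microbe_labels if axis == "microbe" else Y.disease_labels
    if S.labels != labels:
        raise ValueError(f"similarity labels do not match the {axis} axis of Y")

    known = np.flatnonzero(P.sum(axis=1) > 0)
    if known.size == 0:
        raise ValueError("no entity with a known association on this axis")
    lab_arr = np.array(labels)
    sim = S.values
    new = np.zeros_like(P)
    n_truncated = 0
    for q in range(P.shape[0]):
        pool = known[known != q]
        if pool.size == 0:
            continue  # q is the only known entity: profile stays zero
        k_eff = min(cfg.K, pool.size)
        if cfg.K > pool.size:
            n_truncated += 1
        # primary key: descending similarity; tie-break: label, ascending
        order = np.lexsort((lab_arr[pool], -sim[q, pool]))
        nbrs = pool[order[:k_eff]]
        s = sim[q, nbrs]
        w = cfg.alpha ** np.arange(k_eff) * s
        Q = w.sum() if cfg.normalize_with_decay else s.sum()
        if Q > 0:
            new[q] = (w @ P[nbrs]) / Q
    if n_truncated:
        logger.warning(
            "K=%d exceeds the number of known neighbors for %d entities; truncated",
            cfg.K, n_truncated,
        )
    np.clip(new, 0.0, 1.0, out=new)
    values = new if axis == "microbe" else new.T
    return AdjacencyMatrix(values, list(Y.microbe_labels), list(Y.disease_labels))


def combine_and_update(
    Y: AdjacencyMatrix,
    Ym: AdjacencyMatrix,
    Yd: AdjacencyMatrix,
    cfg: WknnConfig | None = None,
) -> AdjacencyMatrix:
    """Average the two axis profiles and max-update the original matrix.

    Y_md = (a1*Ym + a2*Yd) / (a1 + a2); result = max(Y, Y_md) elementwise, so
    every known association stays exactly 1.
    """
    cfg = cfg or WknnConfig()
    if not (Y.same_labels(Ym) and Y.same_labels(Yd)):
        raise ValueError("matrices must share labels and shape")
    Ymd = (cfg.a1 * Ym.values + cfg.a2 * Yd.values) / (cfg.a1 + cfg.a2)
    out = np.maximum(Y.values, Ymd)
    return AdjacencyMatrix(out, list(Y.microbe_labels), list(Y.disease_labels))


def preprocess(
    Y: AdjacencyMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    cfg: WknnConfig | None = None,
) -> AdjacencyMatrix:
    """Full preprocessing: microbe-side + disease-side WKNN, then max-update."""
    cfg = cfg or WknnConfig()
    Ym = wknn_profiles(Y, Sm, axis="microbe", cfg=cfg)
    Yd = wknn_profiles(Y, Sd, axis="disease", cfg=cfg)
    return combine_and_update(Y, Ym, Yd, cfg)
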