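"""Leave-one-out cross-validation with ROC/AUC over held-out association ranks.

Each known association is in turn held out (its adjacency entry set to 0) and
the whole pipeline — GIP similarities, WKNN preprocessing, neighborhood
graphs, factorization — is re-run on the reduced matrix, so no stage ever sees
the test label.  The held-out pair's score is then ranked against the
candidate (unknown) pairs: all of them in global mode, or only those of the
same disease in local mode.  Ties get mid-ranks.

The ROC/AUC engine works on (rank, candidate-count) pairs.  Per fold the
fraction of candidates ranked below the test pair (ties counted half) is
exactly the mid-rank Mann-Whitney U normalization; the reported AUC is its
average over folds, and the emitted ROC staircase integrates (trapezoid) to
the same number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .data import AdjacencyMatrix, AssociationTable, build_adjacency
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["FoldRank", "LoocvResult", "roc_auc", "loocv"]


@dataclass(frozen=True)
class FoldRank:
    microbe: str
    disease: str
    rank: float  # mid-rank; fractional under score ties
    candidates: int


@dataclass
class LoocvResult:
    mode: str
    per_fold_ranks: list[FoldRank]
    roc_points: list[tuple[float, float]]
    auc: float


def roc_auc(
    ranks: Sequence[tuple[float, int]]
) -> tuple[list[tuple[float, float]], float]:
    """ROC staircase and AUC from per-fold (rank, candidate-count) pairs.

    Each fold is normalized to u = (N + 1 - r) / N, the fraction of its N
    candidates ranked below the test pair under the mid-rank convention.
    Thresholds sweep the distinct u values; TPR is the fraction of folds at or
    above threshold and FPR the (per-fold normalized) fraction of candidates
    above it.  The trapezoid integral of the returned points equals mean(u).
    """
    if len(ranks) == 0:
        raise ValueError("no folds supplied")
    u = []
    for r, n_cand in ranks:
        if n_cand < 1:
            raise ValueError("each fold needs at least one candidate")
        if not 1.0 <= r <= n_cand + 1:
            raise ValueError(f"rank {r} outside [1, {n_cand + 1}]")
        u.append((n_cand + 1 - r) / n_cand)
    u = np.asarray(u)
    n_folds = u.size

    vals, counts = np.unique(-u, return_counts=True)  # descending u
    vals = -vals
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tpr = 0.0
    for v, c in zip(vals, counts):
        fpr = 1.0 - v
        if fpr > points[-1][0]:
            points.append((fpr, tpr))
        tpr += c / n_folds
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs, ys = zip(*points)
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def loocv(
    table: AssociationTable,
    sdm: Optional[SimilarityMatrix] = None,
    mode: str = "global",
    cfg=None,
    score_fn: Optional[Callable[[AdjacencyMatrix], AdjacencyMatrix]] = None,
) -> LoocvResult:
    """Leave-one-out cross-validation over every known association.

    ``score_fn`` maps a reduced binary adjacency matrix to a score matrix; by
    default it is the full prediction pipeline under ``cfg`` (a RunConfig).
    With ``cfg.fast_mode`` the GIP/integrated similarities are computed once on
    the full matrix and reused across folds — faster but optimistic, since the
    held-out label then influences the similarities.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    from . import pipeline  # local import; pipeline orchestrates this module too

    if cfg is None:
        cfg = pipeline.RunConfig()
    Y = build_adjacency(table)
    V = Y.values
    held = [(i, j) for i, j in zip(*np.nonzero(V == 1.0))]
    if len(held) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")

    sims = None
    if score_fn is None and getattr(cfg, "fast_mode", False):
        sims = pipeline.compute_similarities(Y, sdm, cfg)
        logger.warning("fast_mode: similarities reused across folds (optimistic)")

    unknown_mask = V == 0.0
    folds: list[FoldRank] = []
    for i, j in held:
        reduced = Y.copy()
        reduced.values[i, j] = 0.0
        if score_fn is not None:
            scores = score_fn(reduced)
        else:
            scores, _ = pipeline.compute_scores(reduced, sdm, cfg, sims=sims)
        if not scores.same_labels(Y):
            raise ValueError("score function changed the label set")
        sv = scores.values
        s = sv[i, j]
        if mode == "global":
            cand = sv[unknown_mask]
        else:
            cand = sv[unknown_mask[:, j], j]
        if cand.size == 0:
            raise ValueError("fold has no candidate pairs to rank against")
        rank = 1.0 + float((cand > s).sum()) + 0.5 * float((cand == s).sum())
        folds.append(
            FoldRank(Y.microbe_labels[i], Y.disease_labels[j], rank, int(cand.size))
        )
    roc_points, auc = roc_auc([(f.rank, f.candidates) for f in folds])
    logger.info("%s LOOCV: %d folds, AUC %.4f", mode, len(folds), auc)
    return LoocvResult(mode, folds, roc_points, auc)
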