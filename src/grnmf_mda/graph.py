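"""Neighborhood/cluster weight graphs and graph Laplacians for regularization.

The factorization is regularized toward the local geometry of microbe space
and disease space.  For each space a sparse weight matrix X is built from the
p-nearest-neighbor structure of the similarity matrix together with an
overlapping clustering (a simplified greedy variant of the ClusterONE
cohesiveness algorithm):

    X(i,j) = 1    if i, j are mutual p-neighbors AND share a cluster
    X(i,j) = 0    if neither is a p-neighbor of the other AND they share none
    X(i,j) = 0.5  otherwise (mixed evidence)

The regularization graph is then S* = X .* S, with degree matrix D (row sums)
and Laplacian L = D - S*, which is symmetric positive semi-definite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "RegularizedGraph",
    "cluster_one",
    "neighbor_weight_matrix",
    "masked_graph",
    "build_regularized_graph",
    "read_cluster_file",
]

# minimal strict improvement for a greedy move; guards float-noise cycling
_GAIN_TOL = 1e-12


@dataclass
class ClusterSet:
    """Possibly overlapping clusters of entity labels."""

    clusters: list[frozenset[str]]
    method_tag: str = "cluster_one"

    def co_membership(self, labels: list[str]) -> np.ndarray:
        """Boolean matrix: True where two labels co-occur in >=1 cluster."""
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        share = np.zeros((n, n), dtype=bool)
        for cl in self.clusters:
            members = [idx[lab] for lab in cl if lab in idx]
            share[np.ix_(members, members)] = True
        return share


@dataclass
class RegularizedGraph:
    """Masked similarity graph S* with degree matrix D and Laplacian L = D - S*."""

    weights: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        row_sums = np.abs(self.laplacian.sum(axis=1)).max(initial=0.0)
        if row_sums > 1e-10:
            raise ValueError(f"Laplacian rows do not sum to 0 (max |sum| {row_sums:g})")
        if np.abs(self.laplacian - self.laplacian.T).max(initial=0.0) > 1e-10:
            raise ValueError("Laplacian is not symmetric")

    @property
    def degree_vector(self) -> np.ndarray:
        return np.diag(self.degree)


def _cohesiveness(w_in: float, w_bound: float) -> float:
    denom = w_in + w_bound
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(A: np.ndarray, seed: int, order_key: np.ndarray) -> set[int]:
    """Greedy cohesiveness maximization from one seed: best add/remove moves.

    ``order_key`` maps vertex index -> rank of its label in sorted order, used
    for deterministic tie-breaking.  The seed itself is never removed.
    """
    n = A.shape[0]
    degree = A.sum(axis=1)
    members = {seed}
    for _ in range(10 * n):  # each accepted move strictly improves cohesiveness
        inside = np.fromiter(members, dtype=int)
        link = A[:, inside].sum(axis=1)  # weight from each vertex into the cluster
        w_in = link[inside].sum() / 2.0
        w_bound = (degree[inside] - link[inside]).sum()
        coh = _cohesiveness(w_in, w_bound)
        best: tuple | None = None  # (-coh, move_pref, label_rank, vertex, is_add)
        for v in range(n):
            if v in members:
                if v == seed or len(members) == 1:
                    continue
                lv = link[v]
                cand = _cohesiveness(w_in - lv, w_bound + lv - (degree[v] - lv))
                key = (-cand, 1, order_key[v], v, False)
            else:
                lv = link[v]
                cand = _cohesiveness(w_in + lv, w_bound - lv + (degree[v] - lv))
                key = (-cand, 0, order_key[v], v, True)
            if cand > coh + _GAIN_TOL and (best is None or key < best):
                best = key
        if best is None:
            break
        _, _, _, v, is_add = best
        if is_add:
            members.add(v)
        else:
            members.discard(v)
    return members


def cluster_one(
    S: SimilarityMatrix,
    density_threshold: float = 0.5,
    merge_overlap: float = 0.8,
) -> ClusterSet:
    """Simplified ClusterONE: greedy cohesive growth, density filter, Jaccard merge.

    Clusters are seeded from the not-yet-covered vertex of highest weighted
    degree and grown/pruned to maximize cohesiveness w_in / (w_in + w_bound).
    Grown clusters with internal density (mean pairwise weight) below
    ``density_threshold`` are discarded; retained cluster pairs with Jaccard
    overlap >= ``merge_overlap`` are merged.  Vertices covered by no retained
    cluster come back as singletons, so every entity is assigned.
    """
    A = S.values.copy()
    np.fill_diagonal(A, 0.0)
    labels = S.labels
    n = len(labels)
    order_key = np.argsort(np.argsort(np.array(labels)))  # label rank per index
    degree = A.sum(axis=1)

    seedable = set(range(n))
    kept: list[frozenset[int]] = []
    while seedable:
        seed = min(seedable, key=lambda v: (-degree[v], order_key[v]))
        members = _grow_cluster(A, seed, order_key)
        size = len(members)
        if size > 1:
            inside = np.fromiter(members, dtype=int)
            w_in = A[np.ix_(inside, inside)].sum() / 2.0
            density = 2.0 * w_in / (size * (size - 1))
        else:
            density = 0.0
        if density >= density_threshold:
            kept.append(frozenset(members))
            seedable -= members
        else:
            seedable.discard(seed)

    # merge highly overlapping clusters (Jaccard on member sets)
    merged = True
    while merged and len(kept) > 1:
        merged = False
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                inter = len(kept[a] & kept[b])
                union = len(kept[a] | kept[b])
                if union and inter / union >= merge_overlap:
                    kept[a] = kept[a] | kept[b]
                    del kept[b]
                    merged = True
                    break
            if merged:
                break

    covered = set().union(*kept) if kept else set()
    clusters = [frozenset(labels[v] for v in cl) for cl in kept]
    clusters += [frozenset({labels[v]}) for v in sorted(set(range(n)) - covered)]
    return ClusterSet(clusters)


def neighbor_weight_matrix(
    S: SimilarityMatrix, clusters: ClusterSet, p: int = 5
) -> np.ndarray:
    """Three-valued weight matrix from p-NN structure and cluster co-membership.

    Entry 1 for mutual neighbors sharing a cluster, 0 when neither relation
    holds, 0.5 for mixed evidence; diagonal fixed to 1.  Symmetric by
    construction (all three conditions are symmetric in i, j).
    """
    n = S.n
    if not 1 <= p < n:
        raise ValueError(f"p must satisfy 1 <= p < {n}, got {p}")
    sim = S.values
    lab_arr = np.array(S.labels)
    nbr = np.zeros((n, n), dtype=bool)
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = np.lexsort((lab_arr[others], -sim[i, others]))
        nbr[i, others[order[:p]]] = True
    share = clusters.co_membership(S.labels)
    mutual = nbr & nbr.T
    neither = ~nbr & ~nbr.T
    X = np.full((n, n), 0.5)
    X[mutual & share] = 1.0
    X[neither & ~share] = 0.0
    np.fill_diagonal(X, 1.0)
    return X


def masked_graph(S: SimilarityMatrix, X: np.ndarray) -> RegularizedGraph:
    """S* = X .* S with degree matrix and Laplacian L = D - S*."""
    X = np.asarray(X, dtype=float)
    if X.shape != S.values.shape:
        raise ValueError("weight matrix shape does not match similarity matrix")
    if np.abs(X - X.T).max(initial=0.0) > 1e-12:
        raise ValueError("weight matrix must be symmetric")
    Sstar = X * S.values
    D = np.diag(Sstar.sum(axis=1))
    L = D - Sstar
    return RegularizedGraph(Sstar, D, L, list(S.labels))


def build_regularized_graph(
    S: SimilarityMatrix,
    p: int = 5,
    density_threshold: float = 0.5,
    merge_overlap: float = 0.8,
    clusters: Optional[ClusterSet] = None,
) -> RegularizedGraph:
    """Convenience: cluster (unless supplied), build X, mask the similarity."""
    p = min(p, S.n - 1)
    if clusters is None:
        clusters = cluster_one(S, density_threshold, merge_overlap)
    X = neighbor_weight_matrix(S, clusters, p)
    return masked_graph(S, X)


def read_cluster_file(path: str | Path, labels: list[str]) -> ClusterSet:
    """Read externally supplied clusters: one cluster per line, tab-separated."""
    known = set(labels)
    clusters = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        members = [x.strip() for x in line.split("\t") if x.strip()]
        unknown = [x for x in members if x not in known]
        if unknown:
            raise ValueError(f"{path}: line {lineno}: unknown labels {unknown}")
        clusters.append(frozenset(members))
    return ClusterSet(clusters, method_tag="external")
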