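"""Synthetic microbe-disease fixtures with planted low-rank structure.

The generator emulates the shape of a curated association catalogue: a sparse
binary bipartite matrix (a few hundred microbes by a few dozen diseases at
full scale), built by thresholding a planted low-rank nonnegative score
matrix, plus a consistent noisy disease-similarity matrix.  Entities are
assigned to latent groups with high within-group factor loadings, which gives
the block/cluster structure the neighborhood-graph stage is meant to find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AdjacencyMatrix, AssociationRecord, AssociationTable
from .similarity import SimilarityMatrix

__all__ = ["FixtureSpec", "generate", "duplicate_some"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults give a small but non-trivial instance (60 x 25, planted rank 4,
    ~120 associations); ``noise_flip_prob`` models rare curation errors and
    ``sdm_noise_sd`` measurement noise on the external disease similarity.
    """

    n_microbes: int = 60
    n_diseases: int = 25
    true_rank: int = 4
    density: float = 0.08
    noise_flip_prob: float = 0.01
    sdm_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rank < 1 or self.true_rank > min(self.n_microbes, self.n_diseases):
            raise ValueError("true_rank must be in [1, min(m, n)]")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if not 0.0 <= self.noise_flip_prob < 1.0:
            raise ValueError("noise_flip_prob must lie in [0, 1)")
        if self.sdm_noise_sd < 0:
            raise ValueError("sdm_noise_sd must be nonnegative")
        if self.density * self.n_microbes * self.n_diseases < self.true_rank:
            raise ValueError("too few planted associations for the requested rank")


def _block_factors(n: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative factor matrix with one dominant latent group per entity."""
    groups = (np.arange(n) * r) // n  # contiguous, near-equal groups
    F = rng.uniform(0.0, 0.05, size=(n, r))
    F[np.arange(n), groups] = rng.uniform(0.6, 1.0, size=n)
    return F


def generate(
    spec: FixtureSpec,
) -> tuple[AssociationTable, AdjacencyMatrix, SimilarityMatrix]:
    """Generate (association table, ground-truth score matrix, disease SDM).

    The true score matrix P = W0 H0^T (rescaled to [0, 1]) has numerical rank
    <= true_rank.  The binary adjacency takes the top ``density`` fraction of
    P's cells, then flips each cell independently with ``noise_flip_prob``.
    The SDM is the cosine similarity of the disease factor rows plus Gaussian
    noise, clipped, symmetrized, with unit diagonal.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, r = spec.n_microbes, spec.n_diseases, spec.true_rank
    microbe_labels = [f"M{i + 1:04d}" for i in range(m)]
    disease_labels = [f"D{j + 1:03d}" for j in range(n)]

    W0 = _block_factors(m, r, rng)
    H0 = _block_factors(n, r, rng)
    P = W0 @ H0.T
    P /= P.max()

    q = int(round(spec.density * m * n))
    flat_order = np.argsort(-P, axis=None, kind="stable")
    Y = np.zeros(m * n)
    Y[flat_order[:q]] = 1.0
    Y = Y.reshape(m, n)
    if spec.noise_flip_prob > 0:
        flips = rng.random((m, n)) < spec.noise_flip_prob
        Y = np.where(flips, 1.0 - Y, Y)
    if Y.sum() < 2:
        raise ValueError("fixture degenerated to fewer than 2 associations")

    records = [
        AssociationRecord(microbe_labels[i], disease_labels[j], f"EV{k + 1:05d}")
        for k, (i, j) in enumerate(zip(*np.nonzero(Y == 1.0)))
    ]
    table = AssociationTable(records)

    norms = np.linalg.norm(H0, axis=1, keepdims=True)
    C = (H0 / norms) @ (H0 / norms).T
    if spec.sdm_noise_sd > 0:
        noise = rng.normal(0.0, spec.sdm_noise_sd, size=(n, n))
        C = C + (noise + noise.T) / 2.0
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    sdm = SimilarityMatrix(C, disease_labels)

    truth = AdjacencyMatrix(P, microbe_labels, disease_labels)
    return table, truth, sdm


def duplicate_some(
    table: AssociationTable, n_dups: int, seed: int = 0
) -> AssociationTable:
    """Append ``n_dups`` duplicate records (fresh evidence ids) to the table.

    Exercises the deduplication path of adjacency construction: the unique
    pair set is unchanged by design.
    """
    if n_dups < 0 or n_dups > len(table):
        raise ValueError("n_dups must lie in [0, len(table)]")
    if n_dups == 0:
        return AssociationTable(list(table.records))
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(table), size=n_dups, replace=True)
    extra = [
        AssociationRecord(
            table.records[i].microbe, table.records[i].disease, f"DUP{k + 1:05d}"
        )
        for k, i in enumerate(picks)
    ]
    return AssociationTable(list(table.records) + extra)
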