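"""Gaussian interaction profile (GIP) kernel similarity and similarity integration.

The GIP kernel scores two microbes (or diseases) by a Gaussian of the squared
distance between their binary interaction profiles — the rows (or columns) of
the adjacency matrix.  The bandwidth is the user bandwidth gamma' normalized by
the mean squared profile norm, so the kernel adapts to the overall density of
the association network.  An external symptom-based disease similarity matrix
(SDM), when available, is averaged with the disease GIP kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import AdjacencyMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "gip_kernel",
    "integrate_disease_similarity",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "sanitize_similarity",
]

_SYM_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with labels.

    ``bandwidth_used`` records the effective GIP bandwidth (gamma_m or gamma_d)
    when the matrix is kernel-derived.
    """

    values: np.ndarray
    labels: list[str]
    bandwidth_used: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite similarity values")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min(initial=0.0) < -1e-12 or self.values.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def gip_kernel(
    Y: AdjacencyMatrix, axis: str = "microbe", gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel similarity over rows (``axis='microbe'``) or columns of Y.

    S(i,j) = exp(-gamma * ||y_i - y_j||^2) with
    gamma = gamma' / mean_i ||y_i||^2.  Y must be binary with at least one
    association overall; individual all-zero profiles are fine (they simply
    contribute 0 to the normalization sum).
    """
    if axis not in ("microbe", "disease"):
        raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if not Y.is_binary():
        raise ValueError("GIP kernel requires a binary adjacency matrix")
    X = Y.values if axis == "microbe" else Y.values.T
    labels = Y.microbe_labels if axis == "microbe" else Y.disease_labels
    mean_sq_norm = float((X**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValueError("adjacency matrix has no associations; bandwidth undefined")
    gamma = gamma_prime / mean_sq_norm
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    S = np.exp(-gamma * D2)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(labels), bandwidth_used=gamma)


def sanitize_similarity(values: np.ndarray, context: str = "similarity") -> np.ndarray:
    """Clip to [0, 1] and symmetrize by averaging with the transpose.

    Changes larger than 1e-9 are logged — an externally supplied matrix should
    already satisfy the invariants.
    """
    values = np.asarray(values, dtype=float)
    clipped = np.clip(values, 0.0, 1.0)
    sym = (clipped + clipped.T) / 2.0
    change = float(np.abs(sym - values).max(initial=0.0))
    if change > 1e-9:
        logger.warning("%s: clipped/symmetrized with max change %.3g", context, change)
    return sym


def integrate_disease_similarity(
    gip: SimilarityMatrix,
    sdm: Optional[SimilarityMatrix] = None,
    strict: bool = False,
) -> SimilarityMatrix:
    """Average the disease GIP kernel with the symptom-based similarity.

    S_d = (S_gip + SDM) / 2, aligned by disease label.  Diseases missing from
    the SDM contribute 0 (with a warning), or raise in strict mode.  Without an
    SDM the GIP kernel passes through unchanged.
    """
    if sdm is None:
        logger.warning("no symptom-based similarity supplied; using GIP kernel alone")
        return gip
    idx = {lab: i for i, lab in enumerate(sdm.labels)}
    missing = [lab for lab in gip.labels if lab not in idx]
    if missing:
        if strict:
            raise ValueError(f"diseases absent from SDM: {missing}")
        logger.warning(
            "%d disease(s) absent from SDM get similarity 0: %s", len(missing), missing
        )
    present = [k for k, lab in enumerate(gip.labels) if lab in idx]
    src = [idx[gip.labels[k]] for k in present]
    aligned = np.zeros((gip.n, gip.n))
    aligned[np.ix_(present, present)] = sdm.values[np.ix_(src, src)]
    out = (gip.values + aligned) / 2.0
    return SimilarityMatrix(out, list(gip.labels))


def read_similarity_matrix(path: str | Path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a square labelled similarity TSV; values are clipped/symmetrized."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    values = sanitize_similarity(df.to_numpy(dtype=float), context=str(path))
    return SimilarityMatrix(values, labels)


def write_similarity_matrix(
    S: SimilarityMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = pd.DataFrame(S.values, index=S.labels, columns=S.labels)
    df.to_csv(path, sep=delimiter, float_format="%.17g")
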