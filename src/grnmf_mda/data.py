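"""Association tables and labelled adjacency/score matrices.

The raw input is a curated list of (microbe, disease) pairs, possibly with an
evidence identifier and possibly containing duplicate pairs backed by different
evidences.  The list is matrix-encoded as a binary adjacency matrix Y with one
row per microbe and one column per disease; after profile preprocessing the
matrix becomes real-valued in [0, 1], and the final prediction scores reuse the
same labelled-matrix container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "AdjacencyMatrix",
    "ParseError",
    "read_association_table",
    "write_association_table",
    "build_adjacency",
    "write_score_matrix",
    "read_score_matrix",
    "rank_predictions",
]


class ParseError(ValueError):
    """Raised when an association file cannot be parsed."""


@dataclass(frozen=True)
class AssociationRecord:
    microbe: str
    disease: str
    evidence: Optional[str] = None


@dataclass
class AssociationTable:
    """Ordered list of microbe-disease association records.

    Duplicate (microbe, disease) pairs are allowed — curated catalogues often
    list the same pair once per supporting publication.
    """

    records: list[AssociationRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if not rec.microbe or not rec.disease:
                raise ValueError("association records need non-empty labels")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def unique_pairs(self) -> set[tuple[str, str]]:
        return {(r.microbe, r.disease) for r in self.records}


@dataclass
class AdjacencyMatrix:
    """Real m x n matrix with row labels (microbes) and column labels (diseases).

    Row i / column j are permanently bound to their labels; label lists must be
    duplicate-free.  Entries are exactly 0/1 for a freshly built adjacency and
    real-valued afterwards (preprocessed profiles, prediction scores).
    """

    values: np.ndarray
    microbe_labels: list[str]
    disease_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.microbe_labels = [str(x) for x in self.microbe_labels]
        self.disease_labels = [str(x) for x in self.disease_labels]
        if self.values.ndim != 2:
            raise ValueError("adjacency values must be 2-D")
        m, n = self.values.shape
        if m != len(self.microbe_labels) or n != len(self.disease_labels):
            raise ValueError("label lists do not match matrix shape")
        if len(set(self.microbe_labels)) != m or len(set(self.disease_labels)) != n:
            raise ValueError("duplicate labels")
        self._mi = {lab: i for i, lab in enumerate(self.microbe_labels)}
        self._di = {lab: j for j, lab in enumerate(self.disease_labels)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def microbe_index(self, label: str) -> int:
        return self._mi[label]

    def disease_index(self, label: str) -> int:
        return self._di[label]

    def copy(self) -> "AdjacencyMatrix":
        return AdjacencyMatrix(
            self.values.copy(), list(self.microbe_labels), list(self.disease_labels)
        )

    def same_labels(self, other: "AdjacencyMatrix") -> bool:
        return (
            self.microbe_labels == other.microbe_labels
            and self.disease_labels == other.disease_labels
        )


def read_association_table(
    path: str | Path, delimiter: str = "\t", header: bool = False
) -> AssociationTable:
    """Read a delimited microbe/disease[/evidence] pair list.

    Blank lines and lines starting with ``#`` are skipped.  ``header=True``
    drops the first non-comment line.  Fields are whitespace-trimmed; labels
    compare case-sensitively afterwards.
    """
    text = Path(path).read_text()
    records: list[AssociationRecord] = []
    skipped_header = not header
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        if not skipped_header:
            skipped_header = True
            continue
        parts = raw.split(delimiter)
        if len(parts) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected >=2 fields, got {len(parts)}"
            )
        microbe, disease = parts[0].strip(), parts[1].strip()
        evidence = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        if not microbe or not disease:
            raise ParseError(f"{path}: line {lineno}: empty label")
        records.append(AssociationRecord(microbe, disease, evidence))
    if not records:
        raise ParseError(f"{path}: no association records found")
    return AssociationTable(records)


def write_association_table(
    table: AssociationTable, path: str | Path, delimiter: str = "\t"
) -> None:
    lines = []
    for rec in table.records:
        fields = [rec.microbe, rec.disease]
        if rec.evidence is not None:
            fields.append(rec.evidence)
        for f in fields:
            if delimiter in f or "\n" in f:
                raise ValueError(f"label/evidence {f!r} contains the delimiter")
        lines.append(delimiter.join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def build_adjacency(table: AssociationTable) -> AdjacencyMatrix:
    """Matrix-encode the pair list: Y(i,j)=1 iff the pair occurs at least once.

    Duplicate records collapse silently (the collapsed count is logged); labels
    are the sorted unique names, which fixes a deterministic row/column order.
    """
    pairs = table.unique_pairs
    n_dup = len(table) - len(pairs)
    if n_dup:
        logger.info(
            "collapsed %d duplicate association records (%d -> %d unique pairs)",
            n_dup, len(table), len(pairs),
        )
    microbes = sorted({m for m, _ in pairs})
    diseases = sorted({d for _, d in pairs})
    mi = {m: i for i, m in enumerate(microbes)}
    di = {d: j for j, d in enumerate(diseases)}
    Y = np.zeros((len(microbes), len(diseases)))
    for m, d in pairs:
        Y[mi[m], di[d]] = 1.0
    return AdjacencyMatrix(Y, microbes, diseases)


def write_score_matrix(
    scores: AdjacencyMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a labelled matrix as TSV: header row = diseases, first column = microbes.

    Values are written with 17 significant digits so a read-back round-trips to
    better than 1e-12 relative.  Labels containing the delimiter are rejected.
    """
    if not np.isfinite(scores.values).all():
        raise ValueError("score matrix contains non-finite values")
    for lab in (*scores.microbe_labels, *scores.disease_labels):
        if delimiter in lab or "\n" in lab:
            raise ValueError(f"label {lab!r} contains the delimiter; refusing to write")
    df = pd.DataFrame(
        scores.values, index=scores.microbe_labels, columns=scores.disease_labels
    )
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_score_matrix(path: str | Path, delimiter: str = "\t") -> AdjacencyMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return AdjacencyMatrix(
        df.to_numpy(dtype=float), [str(x) for x in df.index], [str(x) for x in df.columns]
    )


def rank_predictions(
    scores: AdjacencyMatrix,
    known: AdjacencyMatrix,
    disease_label: str,
    top: Optional[int] = None,
) -> list[tuple[str, float, int]]:
    """Rank candidate microbes for one disease by descending predicted score.

    Only pairs unknown in ``known`` (entry 0) are candidates; ties are broken
    by microbe label so the list is deterministic.  Ranks start at 1.
    """
    if not scores.same_labels(known):
        raise ValueError("scores and known matrices must share labels")
    if disease_label not in scores._di:
        raise KeyError(disease_label)
    j = scores.disease_index(disease_label)
    cands = [
        (lab, float(scores.values[i, j]))
        for i, lab in enumerate(scores.microbe_labels)
        if known.values[i, j] == 0
    ]
    cands.sort(key=lambda t: (-t[1], t[0]))
    ranked = [(lab, s, r) for r, (lab, s) in enumerate(cands, start=1)]
    return ranked if top is None else ranked[:top]
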