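"""Reading association records, building the adjacency matrix, writing rankings.

The central container is :class:`AssociationMatrix`: a labelled binary
disease x microbe adjacency matrix ``A`` with ``A[i, j] = 1`` iff disease
``i`` has a curated association with microbe ``j``.  Identifier matching is
case-insensitive with whitespace collapsed, but the first-seen spelling is
preserved for output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationRecord",
    "AssociationMatrix",
    "read_associations",
    "build_matrix",
    "write_rankings",
]


def _canon(name: str) -> str:
    """Collapse internal whitespace runs to single spaces and trim."""
    return " ".join(name.split())


def _key(name: str) -> str:
    """Case-insensitive identity key for an identifier."""
    return _canon(name).casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One curated disease-microbe association as read from file."""

    disease: str
    microbe: str

    def __post_init__(self) -> None:
        if not _canon(self.disease):
            raise ValueError("empty disease identifier")
        if not _canon(self.microbe):
            raise ValueError("empty microbe identifier")


@dataclass
class AssociationMatrix:
    """Binary disease x microbe adjacency matrix with identifier lists.

    Attributes
    ----------
    diseases, microbes
        Unique identifiers in first-appearance order (first-seen casing).
    A
        Float array of shape ``(len(diseases), len(microbes))`` with entries
        in {0, 1}; the number of ones equals the number of distinct records.
    """

    diseases: list[str]
    microbes: list[str]
    A: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match identifier lists "
                f"({len(self.diseases)} diseases x {len(self.microbes)} microbes)"
            )
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """The distinct (disease, microbe) pairs encoded by the matrix."""
        return [
            (self.diseases[i], self.microbes[j]) for i, j in np.argwhere(self.A == 1)
        ]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.diseases), list(self.microbes), self.A.copy())

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write the known pairs back out as a two-column TSV (no header)."""
        with open(path, "w") as fh:
            for d, m in self.pairs():
                fh.write(f"{d}\t{m}\n")


def read_associations(
    path: str | os.PathLike,
    disease_col: int = 0,
    microbe_col: int = 1,
    sep: str = "\t",
    header: bool = False,
    comment: str = "#",
) -> list[AssociationRecord]:
    """Read raw association records from a delimited text file.

    Records are returned in file order with surrounding whitespace trimmed;
    duplicates are NOT removed here (that happens in :func:`build_matrix`).

    Parameters
    ----------
    disease_col, microbe_col
        Zero-based column positions of the disease and microbe identifiers.
    header
        If True the first non-comment line is skipped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On a line with too few fields or an empty identifier, naming the
        line number.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"association file not found: {path}")
    need = max(disease_col, microbe_col) + 1
    records: list[AssociationRecord] = []
    seen_header = not header
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if comment and line.startswith(comment):
                continue
            if not line.strip():
                continue
            if not seen_header:
                seen_header = True
                continue
            fields = line.rstrip("\n").split(sep)
            if len(fields) < need:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {need} "
                    f"{sep!r}-separated fields, got {len(fields)}"
                )
            try:
                records.append(
                    AssociationRecord(fields[disease_col].strip(), fields[microbe_col].strip())
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def build_matrix(records: list[AssociationRecord]) -> AssociationMatrix:
    """Deduplicate records and assemble the binary adjacency matrix.

    Identifiers are matched case-insensitively with internal whitespace
    collapsed; row/column order is first appearance in ``records``.  The
    number of 1-entries equals the number of distinct pairs.
    """
    if not records:
        raise ValueError("cannot build an association matrix from zero records")
    d_index: dict[str, int] = {}
    m_index: dict[str, int] = {}
    diseases: list[str] = []
    microbes: list[str] = []
    pairs: set[tuple[int, int]] = set()
    for rec in records:
        dk, mk = _key(rec.disease), _key(rec.microbe)
        if dk not in d_index:
            d_index[dk] = len(diseases)
            diseases.append(_canon(rec.disease))
        if mk not in m_index:
            m_index[mk] = len(microbes)
            microbes.append(_canon(rec.microbe))
        pairs.add((d_index[dk], m_index[mk]))
    A = np.zeros((len(diseases), len(microbes)))
    rows, cols = zip(*pairs)
    A[rows, cols] = 1.0
    return AssociationMatrix(diseases, microbes, A)


def rank_table(
    W: np.ndarray,
    assoc: AssociationMatrix,
    top_k: int = 10,
    known_filter: bool = True,
) -> pd.DataFrame:
    """Per-disease candidate ranking as a DataFrame (disease, rank, microbe, score).

    With ``known_filter`` on, pairs already known (``A = 1``) are excluded.
    Candidates are sorted by descending score; ties break by ascending
    column index.  At most ``top_k`` rows per disease, fewer if fewer
    candidates exist.
    """
    W = np.asarray(W, dtype=float)
    if W.shape != assoc.A.shape:
        raise ValueError(f"score matrix shape {W.shape} != adjacency shape {assoc.A.shape}")
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    rows = []
    cols = np.arange(assoc.n_microbes)
    for i, disease in enumerate(assoc.diseases):
        cand = cols[assoc.A[i] == 0] if known_filter else cols
        # lexsort: primary key last -> negated score desc, ties by column index asc
        order = cand[np.lexsort((cand, -W[i, cand]))][:top_k]
        for rank, j in enumerate(order, start=1):
            rows.append((disease, rank, assoc.microbes[j], W[i, j]))
    return pd.DataFrame(rows, columns=["disease", "rank", "microbe", "score"])


def write_rankings(
    W: np.ndarray,
    assoc: AssociationMatrix,
    path: str | os.PathLike,
    top_k: int = 10,
    known_filter: bool = True,
) -> pd.DataFrame:
    """Write :func:`rank_table` output as TSV; returns the table."""
    table = rank_table(W, assoc, top_k=top_k, known_filter=known_filter)
    table.to_csv(path, sep="\t", index=False)
    return table
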