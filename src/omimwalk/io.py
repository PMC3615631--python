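"""Tabular I/O for similarity matrices, association lists and predictions.

All formats are plain TSV (delimiter configurable where noted):

* similarity matrix — labeled square table; cell [0,0] is an arbitrary
  corner label, row and column headers are disease identifiers;
* associations — two columns (mirna_id, disease_id), optional header;
* predictions — four columns (mirna_id, disease_id, score, rank).

Identifiers are opaque strings; no OMIM-prefix semantics are enforced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12

_OMIM_ID_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric disease-disease phenotype similarity matrix.

    Scores are dimensionless, in [0, 1] (MimMiner-style). Row order equals
    column order equals ``disease_ids`` order.
    """

    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.disease_ids)
        object.__setattr__(self, "disease_ids", ids)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("duplicate disease identifiers")
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} ids")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite similarity value")
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("similarity value out of range [0, 1]")
        if vals.size and np.abs(vals - vals.T).max() > SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetric beyond tolerance {SYMMETRY_TOL:g}"
            )

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    def index_of(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id {disease_id!r}") from None


@dataclass(frozen=True)
class AssociationSet:
    """Verified (miRNA, OMIM disease) pairs.

    ``mirna_ids`` and ``disease_ids`` are the sorted distinct identifiers
    occurring in ``pairs``; duplicates in the input are collapsed upstream.
    """

    pairs: frozenset[tuple[str, str]]
    mirna_ids: tuple[str, ...] = field(init=False)
    disease_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        pairs = frozenset((str(m), str(d)) for m, d in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(
            self, "mirna_ids", tuple(sorted({m for m, _ in pairs}))
        )
        object.__setattr__(
            self, "disease_ids", tuple(sorted({d for _, d in pairs}))
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def diseases_of(self, mirna_id: str) -> set[str]:
        return {d for m, d in self.pairs if m == mirna_id}


@dataclass(frozen=True)
class PredictionRecord:
    """One ranked candidate disease for one miRNA.

    ``score`` is the steady-state visiting probability; ``rank`` is 1-based
    (1 = best) and contiguous within a miRNA's list.
    """

    mirna_id: str
    disease_id: str
    score: float
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.score < 0:
            raise ValueError("score must be non-negative")


def read_similarity_matrix(path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a labeled square similarity matrix from a delimited text file.

    The first row and first column carry disease identifiers; the corner
    cell is ignored. Asymmetry beyond 1e-12 is an error, never silently
    symmetrized.
    """
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(row_ids) != len(col_ids):
        raise ValueError(
            f"non-square matrix: {len(row_ids)} rows, {len(col_ids)} columns"
        )
    if row_ids != col_ids:
        raise ValueError("row labels do not match column labels (same order)")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in similarity matrix: {exc}") from exc
    return SimilarityMatrix(tuple(row_ids), values)


def write_similarity_matrix(
    sim: SimilarityMatrix, path, delimiter: str = "\t"
) -> None:
    """Write a similarity matrix in the same labeled layout read back by
    :func:`read_similarity_matrix` (full float precision)."""
    df = pd.DataFrame(
        sim.values, index=list(sim.disease_ids), columns=list(sim.disease_ids)
    )
    df.to_csv(path, sep=delimiter, index_label="disease_id", float_format="%.17g")


def _looks_like_header(fields: list[str]) -> bool:
    # a header line is one whose second field is non-numeric and matches no
    # OMIM-ID pattern
    return not _OMIM_ID_RE.match(fields[1])


def read_associations(path) -> AssociationSet:
    """Read a two-column (mirna_id, disease_id) TSV.

    A header line is auto-detected. Duplicate pairs are collapsed with a
    logged warning reporting the count.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    unique = frozenset(pairs)
    n_dup = len(pairs) - len(unique)
    if n_dup:
        logger.warning("collapsed %d duplicate association pair(s)", n_dup)
    return AssociationSet(unique)


def write_associations(assoc: AssociationSet, path) -> None:
    """Write an association set as a sorted two-column TSV with header."""
    df = pd.DataFrame(sorted(assoc.pairs), columns=["mirna_id", "disease_id"])
    df.to_csv(path, sep="\t", index=False)


def write_predictions(records, path) -> None:
    """Write prediction records as a four-column TSV.

    Rows are ordered by miRNA id ascending then rank ascending; scores are
    printed with >= 6 significant digits.
    """
    rows = sorted(records, key=lambda r: (r.mirna_id, r.rank))
    df = pd.DataFrame(
        [(r.mirna_id, r.disease_id, r.score, r.rank) for r in rows],
        columns=["mirna_id", "disease_id", "score", "rank"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_predictions(path) -> list[PredictionRecord]:
    """Read back a predictions TSV written by :func:`write_predictions`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"mirna_id": str, "disease_id": str}
    )
    return [
        PredictionRecord(r.mirna_id, r.disease_id, float(r.score), int(r.rank))
        for r in df.itertuples(index=False)
    ]
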