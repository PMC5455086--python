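"""Aligned multiple sequence alignments anchored on a query row.

The container is a rectangular symbol matrix whose row 0 is the query
(master) sequence.  Columns of the alignment are the coordinate system for
everything downstream: per-position weighting blocks are column intervals,
and PSSM positions are the query's non-gap columns.

Coordinates are 0-based and extents are inclusive throughout the library;
1-based numbering appears only in human-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: 20 standard amino acids plus gap and the ambiguity codes we pass through.
AMBIGUITY = frozenset("XBZU*")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_SYMBOLS = STANDARD_AA | AMBIGUITY | {GAP}


class MSAFormatError(ValueError):
    """Malformed alignment input (ragged rows, empty file, bad symbol)."""


class MSAValidationError(ValueError):
    """Structurally valid file violating an alignment invariant."""


class ParameterError(ValueError):
    """Out-of-range user parameter."""


@dataclass(frozen=True)
class RowExtent:
    """First/last non-gap column of one alignment row (inclusive)."""

    row: int
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class AlignedMSA:
    """Rectangular alignment; ``rows`` is an (n, L) array of 1-char symbols."""

    def __init__(self, ids: Sequence[str], rows: np.ndarray | Sequence[str]):
        if not isinstance(rows, np.ndarray):
            rows = np.array([list(r) for r in rows], dtype="<U1")
        if rows.ndim != 2:
            raise MSAValidationError("alignment matrix must be 2-dimensional")
        n, L = rows.shape
        if n < 1 or L < 1:
            raise MSAValidationError("alignment must have >= 1 row and >= 1 column")
        if len(ids) != n:
            raise MSAValidationError(
                f"{len(ids)} ids for {n} rows"
            )
        bad = set(np.unique(rows)) - VALID_SYMBOLS
        if bad:
            raise MSAFormatError(f"invalid alignment symbols: {sorted(bad)}")
        for i in range(n):
            if (rows[i] == GAP).all():
                raise MSAValidationError(f"row {ids[i]!r} contains only gaps")
        self.ids = list(ids)
        self.rows = rows

    # -- basic geometry ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    query_row: int = 0

    def query_columns(self) -> np.ndarray:
        """Columns where the query has a residue (the PSSM positions)."""
        return np.flatnonzero(self.rows[self.query_row] != GAP)

    def row_string(self, i: int) -> str:
        return "".join(self.rows[i])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AlignedMSA)
            and self.ids == other.ids
            and self.rows.shape == other.rows.shape
            and bool((self.rows == other.rows).all())
        )

    def __repr__(self) -> str:
        return f"AlignedMSA(n={self.n}, L={self.length}, query={self.ids[0]!r})"


def row_extents(msa: AlignedMSA) -> list[RowExtent]:
    """Per-row first/last non-gap columns.

    These are the pairwise-alignment start/end positions that bound the
    weighting block at each query position.
    """
    out = []
    for i in range(msa.n):
        nz = np.flatnonzero(msa.rows[i] != GAP)
        out.append(RowExtent(row=i, start=int(nz[0]), end=int(nz[-1])))
    return out


def read_aligned_fasta(path: str | Path) -> AlignedMSA:
    """Read an aligned FASTA file; first record is the query/master row.

    Symbols are upper-cased and '.' gaps normalised to '-'.  Unequal record
    lengths, empty input and all-gap rows are rejected.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper().replace(".", GAP))
    if not ids:
        raise MSAFormatError(f"no FASTA records in {path}")
    L = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L:
            raise MSAFormatError(
                f"record {rid!r} has length {len(s)}, expected {L}"
            )
    return AlignedMSA(ids, seqs)


def write_aligned_fasta(msa: AlignedMSA, path: str | Path, header: str | None = None) -> None:
    """Write aligned FASTA; optional provenance goes in the first description."""
    records = []
    for i, rid in enumerate(msa.ids):
        desc = header if (i == 0 and header) else ""
        records.append(SeqRecord(Seq(msa.row_string(i)), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def _internal_gap_runs(row: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, end) of gap runs strictly inside the row's extent."""
    nz = np.flatnonzero(row != GAP)
    start, end = int(nz[0]), int(nz[-1])
    j = start
    while j <= end:
        if row[j] == GAP:
            k = j
            while row[k] == GAP:
                k += 1
            yield (j, k - 1)
            j = k
        else:
            j += 1


def split_rows_on_long_gaps(msa: AlignedMSA, gap_threshold: int = 10) -> AlignedMSA:
    """Split non-query rows at internal gap runs of length >= ``gap_threshold``.

    Mirrors how PSI-BLAST's ``-in_msa`` path fragments aligned sequences that
    contain long deletions (10 aa in the 2.5.0 code line), which is a major
    source of narrow weighting blocks.  Terminal gaps never trigger a split;
    each piece keeps its residues in place with gaps elsewhere and the ids
    gain ``/part1``, ``/part2``, ... suffixes.  The query row is never split.
    """
    if gap_threshold < 1:
        raise ParameterError(f"gap_threshold must be >= 1, got {gap_threshold}")
    new_ids: list[str] = []
    new_rows: list[np.ndarray] = []
    for i in range(msa.n):
        row = msa.rows[i]
        if i == msa.query_row:
            cuts = []
        else:
            cuts = [run for run in _internal_gap_runs(row)
                    if run[1] - run[0] + 1 >= gap_threshold]
        if not cuts:
            new_ids.append(msa.ids[i])
            new_rows.append(row)
            continue
        nz = np.flatnonzero(row != GAP)
        seg_start = int(nz[0])
        bounds: list[tuple[int, int]] = []
        for g0, g1 in cuts:
            bounds.append((seg_start, g0 - 1))
            seg_start = g1 + 1
        bounds.append((seg_start, int(nz[-1])))
        for part, (s, e) in enumerate(bounds, start=1):
            piece = np.full(msa.length, GAP, dtype="<U1")
            piece[s:e + 1] = row[s:e + 1]
            new_ids.append(f"{msa.ids[i]}/part{part}")
            new_rows.append(piece)
    return AlignedMSA(new_ids, np.array(new_rows, dtype="<U1"))
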