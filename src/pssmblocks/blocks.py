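"""Per-position weighting blocks.

For each query position the weighting scheme first restricts the alignment
to the rows with a residue (not a gap) at that position — the *reduced
MSA* — and then bounds the block by the pairwise-alignment start/end
positions closest to the focal column among those rows: the block runs from
the maximum of the reduced rows' extent starts to the minimum of their
extent ends.  Because every reduced row spans the focal column, the focal
column always lies inside the block.

Fragmented or over-extended rows make these blocks collapse to a few
columns (in the worst case a single column), which degenerates the sequence
weights.  ``extend_block`` applies the minimum-block-width (MBW) fix:
blocks narrower than MBW are grown by MBW-1 columns on each side, clamped
at the alignment termini.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, AlignedMSA, ParameterError, row_extents

DEFAULT_MBW = 25


@dataclass(frozen=True)
class Block:
    """Column interval [left, right] used to weight one query position."""

    focal: int
    left: int
    right: int
    reduced_rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (self.left <= self.focal <= self.right):
            raise ValueError(
                f"focal {self.focal} outside block [{self.left}, {self.right}]"
            )

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    @property
    def extent(self) -> tuple[int, int]:
        return (self.left, self.right)


def reduced_rows(msa: AlignedMSA, focal: int) -> tuple[int, ...]:
    """Rows with a residue at ``focal``; always contains the query row."""
    if msa.rows[msa.query_row, focal] == GAP:
        raise ValueError(
            f"column {focal} is a query gap; blocks exist only at query positions"
        )
    return tuple(int(i) for i in np.flatnonzero(msa.rows[:, focal] != GAP))


def block_for_position(msa: AlignedMSA, focal: int) -> Block:
    """Block bounded by the reduced rows' nearest extent starts/ends."""
    rows = reduced_rows(msa, focal)
    extents = row_extents(msa)
    left = max(extents[i].start for i in rows)
    right = min(extents[i].end for i in rows)
    return Block(focal=focal, left=left, right=right, reduced_rows=rows)


def extend_block(block: Block, mbw: int, length: int) -> Block:
    """Apply the minimum-block-width rule.

    Blocks with width < ``mbw`` are extended front and rear by ``mbw - 1``
    columns, clamped to the alignment termini; wider blocks are returned
    unchanged.  ``mbw = 1`` is the identity (the unmodified behaviour).
    """
    if mbw < 1:
        raise ParameterError(f"mbw must be >= 1, got {mbw}")
    if block.width >= mbw:
        return block
    return Block(
        focal=block.focal,
        left=max(0, block.left - (mbw - 1)),
        right=min(length - 1, block.right + (mbw - 1)),
        reduced_rows=block.reduced_rows,
    )


@dataclass
class BlockStats:
    """Diagnostics of block geometry over all query positions.

    Widths are measured before MBW extension — they characterise what the
    unmodified weighting generates, which is the quantity the extension fix
    is judged against.
    """

    widths: list[int]
    query_length: int
    distinct_extents: int
    extent_by_position: dict[int, tuple[int, int]] = field(repr=False, default_factory=dict)

    def narrow_fraction(self, w: int) -> float:
        """Fraction of query positions whose block is narrower than ``w``."""
        if not self.widths:
            return 0.0
        return sum(1 for x in self.widths if x < w) / len(self.widths)

    @property
    def one_aa_ratio(self) -> float:
        """(# width-1 blocks) / (query length)."""
        return sum(1 for x in self.widths if x == 1) / self.query_length

    def width_histogram(self, bins: tuple[int, ...] = (1, 5, 13, 25)) -> dict[str, int]:
        """Counts in [b_k, b_{k+1}) bins, last bin open-ended."""
        edges = list(bins) + [None]
        out: dict[str, int] = {}
        counts = Counter(self.widths)
        for lo, hi in zip(edges[:-1], edges[1:]):
            label = f"{lo}+" if hi is None else f"{lo}-{hi - 1}"
            out[label] = sum(c for w, c in counts.items()
                             if w >= lo and (hi is None or w < hi))
        return out


def block_stats(msa: AlignedMSA) -> BlockStats:
    """Collect one block observation per query position (pre-extension)."""
    cols = msa.query_columns()
    widths: list[int] = []
    extent_by_position: dict[int, tuple[int, int]] = {}
    for c in cols:
        b = block_for_position(msa, int(c))
        widths.append(b.width)
        extent_by_position[int(c)] = b.extent
    return BlockStats(
        widths=widths,
        query_length=len(cols),
        distinct_extents=len(set(extent_by_position.values())),
        extent_by_position=extent_by_position,
    )
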