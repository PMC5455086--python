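"""Position-specific sequence weights over a block.

The weight of row *i* over a block of width *l* is

    W_i = sum over block columns j of  1 / (r_j * n_{a,j} * l)

where ``r_j`` is the number of distinct symbol types in column j (over the
block's reduced rows), ``n_{a,j}`` the count of row i's own symbol ``a``
there.  Gaps inside the block — possible only after MBW extension, since
reduced rows have residues at the focal column — count as a 21st symbol
type.  The formula is self-normalising: within each column the per-row
terms sum to 1/l, so the weights of any block sum to exactly 1.

The weighted residue probability at the focal column is then
P_a = sum of W_i over rows whose focal symbol is a.  For a width-1 block
this degenerates to P_a = 1/r for every observed type, independent of the
actual residue counts — the pathology the MBW extension removes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .blocks import Block
from .msa import AlignedMSA

SUM_TOL = 1e-9


@dataclass(frozen=True)
class ColumnCounts:
    """Distinct-type count r and per-symbol counts for one block column."""

    r: int
    counts: dict[str, int]


@dataclass(frozen=True)
class WeightVector:
    """Per-row weights for one block; values sum to 1."""

    weights: dict[int, float]
    block: Block

    def __getitem__(self, row: int) -> float:
        return self.weights[row]


def column_counts(msa: AlignedMSA, block: Block, column: int) -> ColumnCounts:
    """Symbol counts in one block column over the block's reduced rows.

    The gap symbol, when present (extended blocks only), is counted as its
    own type; ambiguity codes are likewise distinct types.
    """
    if not (block.left <= column <= block.right):
        raise ValueError(f"column {column} outside block {block.extent}")
    counts = Counter(str(msa.rows[i, column]) for i in block.reduced_rows)
    return ColumnCounts(r=len(counts), counts=dict(counts))


def sequence_weights(msa: AlignedMSA, block: Block) -> WeightVector:
    """Evaluate W_i over the block for every reduced row."""
    l = block.width
    totals = dict.fromkeys(block.reduced_rows, 0.0)
    for col in range(block.left, block.right + 1):
        cc = column_counts(msa, block, col)
        for i in block.reduced_rows:
            sym = str(msa.rows[i, col])
            totals[i] += 1.0 / (cc.r * cc.counts[sym] * l)
    s = sum(totals.values())
    assert abs(s - 1.0) <= SUM_TOL, f"weights sum to {s}, expected 1"
    return WeightVector(weights=totals, block=block)


def weighted_frequencies(
    msa: AlignedMSA, block: Block, weights: WeightVector
) -> dict[str, float]:
    """Weighted symbol probabilities at the block's focal column.

    Reduced rows all carry residues at the focal column, so the result is a
    distribution over residue (and possibly ambiguity) symbols; it sums
    to 1 because the weights do.
    """
    if weights.block is not block and weights.block != block:
        raise ValueError("weight vector was computed for a different block")
    freqs: dict[str, float] = {}
    for i in block.reduced_rows:
        sym = str(msa.rows[i, block.focal])
        freqs[sym] = freqs.get(sym, 0.0) + weights[i]
    return freqs
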