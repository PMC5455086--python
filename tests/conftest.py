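"""Shared fixtures and independent brute-force oracles.

The oracles re-derive block extents and sequence weights directly from
their definitions — a literal column scan and exact rational arithmetic —
so they share no code path with the implementation they check.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from pssmblocks import AlignedMSA, Block, FixtureConfig, fragment_row, make_gapless_msa

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_msa(rng: np.random.Generator, max_rows: int = 8, max_cols: int = 12,
               gap_prob: float = 0.3) -> AlignedMSA:
    """Small random MSA with gaps; query row kept gapless for simplicity of
    guaranteeing at least one valid PSSM position per row constraint."""
    n = int(rng.integers(2, max_rows + 1))
    L = int(rng.integers(2, max_cols + 1))
    rows = rng.choice(list(AA20), size=(n, L))
    mask = rng.random((n, L)) < gap_prob
    mask[0] = False  # query gapless
    rows[mask] = "-"
    for i in range(1, n):  # no all-gap rows
        if (rows[i] == "-").all():
            rows[i, int(rng.integers(0, L))] = "A"
    return AlignedMSA([f"s{i}" for i in range(n)], rows)


# -- oracles ---------------------------------------------------------------

def brute_block_extent(msa: AlignedMSA, focal: int) -> tuple[int, int]:
    """Block extent by direct per-row scan of first/last residue columns."""
    rows = [i for i in range(msa.n) if msa.rows[i, focal] != "-"]
    starts, ends = [], []
    for i in rows:
        cols = [c for c in range(msa.length) if msa.rows[i, c] != "-"]
        starts.append(cols[0])
        ends.append(cols[-1])
    return (max(starts), min(ends))


def rational_weights(msa: AlignedMSA, block: Block) -> dict[int, Fraction]:
    """Exact evaluation of W_i = sum_j 1/(r_j * n_aj * l) with Fractions."""
    l = block.right - block.left + 1
    out = {i: Fraction(0) for i in block.reduced_rows}
    for col in range(block.left, block.right + 1):
        counts = Counter(str(msa.rows[i, col]) for i in block.reduced_rows)
        r = len(counts)
        for i in block.reduced_rows:
            a = str(msa.rows[i, col])
            out[i] += Fraction(1, r * counts[a] * l)
    return out


def rational_focal_freqs(msa: AlignedMSA, block: Block) -> dict[str, Fraction]:
    w = rational_weights(msa, block)
    freqs: dict[str, Fraction] = {}
    for i in block.reduced_rows:
        sym = str(msa.rows[i, block.focal])
        freqs[sym] = freqs.get(sym, Fraction(0)) + w[i]
    return freqs


# -- fixtures --------------------------------------------------------------

@pytest.fixture
def toy3_msa() -> AlignedMSA:
    """Three gapless rows AC / AC / AT: the hand-computed weight example."""
    return AlignedMSA(["q", "s1", "s2"], ["AC", "AC", "AT"])


@pytest.fixture
def overlap_cfg() -> FixtureConfig:
    """Ten-row gapless MSA, four residue types per column, row 10 split into
    two fragments overlapping only at column 18 (position 19, 1-based)."""
    return FixtureConfig(n_rows=10, length=40, alphabet_diversity=4,
                         split_row=9, split_col=18, overlap=1, seed=7)


@pytest.fixture
def gapless_msa(overlap_cfg) -> AlignedMSA:
    return make_gapless_msa(overlap_cfg)


@pytest.fixture
def fragmented_msa(gapless_msa, overlap_cfg) -> AlignedMSA:
    return fragment_row(gapless_msa, overlap_cfg.split_row,
                        overlap_cfg.split_col, overlap_cfg.overlap)
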