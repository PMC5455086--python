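"""Deterministic generators for the pathological MSA structures.

Three alignment scenarios are covered, mirroring the ways narrow weighting
blocks arise in practice:

* gapless MSAs with controlled per-column residue diversity — the benign
  baseline where one block covers the whole alignment;
* a gapless MSA with one row fragmented into two pieces that overlap at a
  single column (the library-fragmentation artifact), which collapses the
  block at the overlap column to width one;
* a two-domain query where rows matching domain A over-extend a few
  columns into domain B (homologous over-extension, HOE), producing blocks
  as narrow as the overhang at the junction.

A labeled ranked-hit generator with a tunable ranking quality supplies
inputs for the evaluation statistics.  All randomness flows from a single
integer seed; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import RankedHit
from .msa import GAP, AlignedMSA, ParameterError
from .matrices import AA_ORDER

_AA = np.array(list(AA_ORDER), dtype="<U1")


@dataclass
class FixtureConfig:
    """Parameters of the fragmented-overlap construction."""

    n_rows: int = 10
    length: int = 40
    alphabet_diversity: int = 4
    split_row: int = 9
    split_col: int = 18
    overlap: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.split_col < self.length):
            raise ParameterError("split_col must lie inside the alignment")
        if self.overlap < 1:
            raise ParameterError("overlap must be >= 1")


def _conserved_counts(n: int, k: int) -> list[int]:
    """Allocate n rows over k residue types with geometric dominance.

    Every type gets at least one row; the remainder is split in proportion
    to 4^-i (largest-remainder rounding), so each column has one dominant
    residue and progressively rarer variants — e.g. counts (6, 2, 1, 1)
    for 10 rows and 4 types, a 60/20/10/10 composition typical of a
    conserved alignment column with minor variants.  This is the regime
    where replacing weighted frequencies by the uniform 1/r law distorts
    most, which is the pathology the fixtures exist to exhibit.
    """
    weights = [4.0 ** -i for i in range(k)]
    total = sum(weights)
    shares = [(n - k) * w / total for w in weights]
    counts = [1 + int(s) for s in shares]
    leftover = n - sum(counts)
    order = sorted(range(k), key=lambda i: (-(shares[i] - int(shares[i])), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def make_gapless_msa(config: FixtureConfig) -> AlignedMSA:
    """Gapless n x L MSA with exactly ``alphabet_diversity`` types per column.

    Each column draws a fixed subset of residues of the requested size and
    fills the rows with a dominant-residue composition (see
    :func:`_conserved_counts`), so the per-column diversity is exact and
    the columns resemble conserved positions with minor variants rather
    than uniform noise.
    """
    k = config.alphabet_diversity
    if not (1 <= k <= 20):
        raise ParameterError(f"alphabet_diversity must be in 1..20, got {k}")
    if k > config.n_rows:
        raise ParameterError(
            f"cannot place {k} distinct residues in {config.n_rows} rows"
        )
    rng = np.random.default_rng(config.seed)
    counts = _conserved_counts(config.n_rows, k)
    rows = np.empty((config.n_rows, config.length), dtype="<U1")
    for col in range(config.length):
        subset = rng.choice(_AA, size=k, replace=False)
        column = np.repeat(subset, counts)
        rng.shuffle(column)
        rows[:, col] = column
    ids = [f"seq{i + 1}" for i in range(config.n_rows)]
    ids[0] = "query"
    return AlignedMSA(ids, rows)


def fragment_row(msa: AlignedMSA, row: int, split_col: int, overlap: int) -> AlignedMSA:
    """Replace one row by two overlapping fragments.

    Piece A covers the row's extent start through ``split_col + overlap - 1``;
    piece B covers ``split_col`` through the extent end, so the two pieces
    share exactly ``overlap`` columns.  With overlap 1 this reproduces the
    single-column-overlap artifact that collapses the block there to width
    one.
    """
    if row == msa.query_row:
        raise ParameterError("the query row cannot be fragmented")
    nz = np.flatnonzero(msa.rows[row] != GAP)
    start, end = int(nz[0]), int(nz[-1])
    if not (start <= split_col and split_col + overlap - 1 <= end):
        raise ParameterError(
            f"split window [{split_col}, {split_col + overlap - 1}] outside "
            f"row extent [{start}, {end}]"
        )
    piece_a = np.full(msa.length, GAP, dtype="<U1")
    piece_a[start:split_col + overlap] = msa.rows[row, start:split_col + overlap]
    piece_b = np.full(msa.length, GAP, dtype="<U1")
    piece_b[split_col:end + 1] = msa.rows[row, split_col:end + 1]
    ids = msa.ids[:row] + [f"{msa.ids[row]}a", f"{msa.ids[row]}b"] + msa.ids[row + 1:]
    rows = np.vstack([msa.rows[:row], piece_a, piece_b, msa.rows[row + 1:]])
    return AlignedMSA(ids, rows)


def make_fragmented_msa(config: FixtureConfig) -> AlignedMSA:
    """Gapless baseline with ``split_row`` fragmented at ``split_col``."""
    base = make_gapless_msa(config)
    return fragment_row(base, config.split_row, config.split_col, config.overlap)


def make_hoe_msa(
    domain_a_len: int,
    domain_b_len: int,
    overhang: int,
    n_a: int,
    n_b: int,
    seed: int = 0,
) -> AlignedMSA:
    """Two-domain query with domain-A rows over-extending into domain B.

    The query spans both domains.  ``n_a`` rows cover domain A plus
    ``overhang`` extra columns into domain B; ``n_b`` rows cover domain B
    only.  Where the over-extended rows and the domain-B rows co-occur the
    block narrows to the overhang width.
    """
    if domain_a_len < 1 or domain_b_len < 1:
        raise ParameterError("domain lengths must be >= 1")
    if overhang < 1:
        raise ParameterError("overhang must be >= 1")
    if n_a < 0 or n_b < 0:
        raise ParameterError("row counts must be >= 0")
    rng = np.random.default_rng(seed)
    L = domain_a_len + domain_b_len
    a_end = min(domain_a_len + overhang, L)  # columns covered by HOE rows
    rows = [rng.choice(_AA, size=L)]
    ids = ["query"]
    for i in range(n_a):
        r = np.full(L, GAP, dtype="<U1")
        r[:a_end] = rng.choice(_AA, size=a_end)
        rows.append(r)
        ids.append(f"hoeA{i + 1}")
    for i in range(n_b):
        r = np.full(L, GAP, dtype="<U1")
        r[domain_a_len:] = rng.choice(_AA, size=domain_b_len)
        rows.append(r)
        ids.append(f"domB{i + 1}")
    return AlignedMSA(ids, np.vstack(rows))


def make_ranked_hits(
    n_queries: int,
    tps_per_query: int,
    fps_per_query: int,
    ranking_quality: float,
    seed: int = 0,
) -> list[RankedHit]:
    """Labeled hits with controlled TP-vs-FP ranking quality.

    Quality 1 ranks every TP above every FP (per query); quality 0 the
    reverse; intermediate values interleave with seeded jitter.  E-values
    are distinct, increase with rank, and stay below 1.0 so all hits pass
    the ROC5 filter.
    """
    if not (0.0 <= ranking_quality <= 1.0):
        raise ParameterError("ranking_quality must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hits: list[RankedHit] = []
    n = tps_per_query + fps_per_query
    for qi in range(n_queries):
        keyed = []
        for t in range(tps_per_query):
            keyed.append((t + (1.0 - ranking_quality) * n + 0.5 * rng.random(), "TP", t))
        for f in range(fps_per_query):
            keyed.append((f + ranking_quality * n + 0.5 * rng.random(), "FP", f))
        keyed.sort()
        for rank, (_, label, idx) in enumerate(keyed):
            evalue = 10.0 ** (-8.0 + 7.0 * rank / max(1, n - 1))
            hits.append(
                RankedHit(
                    query_id=f"q{qi + 1}",
                    subject_id=f"{label.lower()}{idx + 1}",
                    evalue=evalue,
                    label=label,
                )
            )
    return hits
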