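"""Assemble per-position weighted frequencies into a log-odds PSSM.

Pipeline per query position (non-gap query column):

    reduced rows -> block -> MBW extension -> sequence weights
    -> weighted focal frequencies -> pseudocounts -> integer log-odds

Scores are half-bit integers (scale 2) against Robinson–Robinson
backgrounds; pseudocounts mix the observed distribution with a
BLOSUM62-derived target as (alpha*P + beta*G)/(alpha + beta), with alpha
the observed diversity minus one.  The ASCII writer emits the familiar
two-table NCBI layout (log-odds, then weighted observed percentages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .blocks import DEFAULT_MBW, block_for_position, extend_block
from .matrices import AA_INDEX, AA_ORDER, background_frequencies, blosum62_conditional
from .msa import AlignedMSA, ParameterError
from .weights import sequence_weights, weighted_frequencies

DEFAULT_BETA = 10.0
DEFAULT_SCALE = 2.0
MIN_PROB = 1e-4


@dataclass(frozen=True)
class PositionProfile:
    position: int          # 1-based index along the ungapped query
    column: int            # 0-based alignment column
    query_residue: str
    freqs: np.ndarray      # pre-pseudocount probabilities over AA_ORDER
    block_width: int       # width actually used for weighting (post-extension)
    raw_width: int         # width before MBW extension
    reduced_count: int     # rows participating at this position
    observations: int      # distinct standard residue types at the focal column


@dataclass
class FrequencyProfile:
    """Pre-pseudocount weighted residue probabilities per query position."""

    positions: list[PositionProfile]

    def freq_matrix(self) -> np.ndarray:
        return np.vstack([p.freqs for p in self.positions])


@dataclass
class PSSM:
    """Integer log-odds scores and rounded observed percentages."""

    query_residues: list[str]
    scores: np.ndarray       # (P, 20) int
    percentages: np.ndarray  # (P, 20) int
    config: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.scores.shape[0]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def standardize_frequencies(raw: dict[str, float], background: np.ndarray) -> np.ndarray:
    """Map a symbol->probability dict onto the 20 standard residues.

    Probability mass on ambiguity symbols (X/B/Z/U/*) is redistributed
    proportionally over the standard-residue mass, or over the background
    when no standard residue was observed, keeping the vector normalised.
    """
    v = np.zeros(20)
    extra = 0.0
    for sym, p in raw.items():
        idx = AA_INDEX.get(sym)
        if idx is None:
            extra += p
        else:
            v[idx] += p
    if extra > 0.0:
        v += extra * (v / v.sum() if v.sum() > 0 else background)
    total = v.sum()
    if total > 0:
        v /= total
    return v


def apply_pseudocounts(
    freq_vector: np.ndarray,
    observations: int,
    beta: float = DEFAULT_BETA,
    conditional: np.ndarray | None = None,
) -> np.ndarray:
    """Mix observed frequencies with substitution-matrix pseudocounts.

    Returns (alpha*P + beta*G)/(alpha + beta) with alpha = observations - 1
    and g_b = sum_a P_a q(b|a).  beta = 0 returns the input unchanged;
    observations = 1 returns the pure pseudocount target.
    """
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    if observations < 1:
        raise ParameterError(f"observations must be >= 1, got {observations}")
    if beta == 0:
        return freq_vector
    if conditional is None:
        conditional = blosum62_conditional()
    alpha = observations - 1
    g = freq_vector @ conditional
    mixed = (alpha * freq_vector + beta * g) / (alpha + beta)
    return mixed / mixed.sum()


def log_odds(
    freq_vector: np.ndarray,
    background: np.ndarray,
    scale: float = DEFAULT_SCALE,
    min_prob: float = MIN_PROB,
) -> np.ndarray:
    """Integer log-odds scores round(scale * log2(P/bg)), P floored at min_prob."""
    if np.any(background <= 0):
        raise ParameterError("background frequencies must all be positive")
    p = np.maximum(freq_vector, min_prob)
    return _round_half_away(scale * np.log2(p / background))


def build_profile(msa: AlignedMSA, mbw: int = DEFAULT_MBW) -> FrequencyProfile:
    """Weighted residue frequencies for every query position."""
    if mbw < 1:
        raise ParameterError(f"mbw must be >= 1, got {mbw}")
    bg = background_frequencies()
    positions: list[PositionProfile] = []
    for k, col in enumerate(msa.query_columns(), start=1):
        col = int(col)
        raw_block = block_for_position(msa, col)
        block = extend_block(raw_block, mbw, msa.length)
        wv = sequence_weights(msa, block)
        raw = weighted_frequencies(msa, block, wv)
        freqs = standardize_frequencies(raw, bg)
        observed_types = {s for s in raw if s in AA_INDEX}
        positions.append(
            PositionProfile(
                position=k,
                column=col,
                query_residue=str(msa.rows[msa.query_row, col]),
                freqs=freqs,
                block_width=block.width,
                raw_width=raw_block.width,
                reduced_count=len(block.reduced_rows),
                observations=max(1, len(observed_types)),
            )
        )
    return FrequencyProfile(positions)


def build_pssm(
    msa: AlignedMSA,
    mbw: int = DEFAULT_MBW,
    beta: float = DEFAULT_BETA,
    pseudocounts: bool = True,
    scale: float = DEFAULT_SCALE,
    min_prob: float = MIN_PROB,
) -> tuple[FrequencyProfile, PSSM]:
    """Full MSA -> (frequency profile, integer PSSM) pipeline."""
    profile = build_profile(msa, mbw=mbw)
    bg = background_frequencies()
    cond = blosum62_conditional() if (pseudocounts and beta > 0) else None
    scores = np.empty((len(profile.positions), 20), dtype=int)
    percentages = np.empty_like(scores)
    for r, pos in enumerate(profile.positions):
        p = pos.freqs
        if cond is not None:
            p = apply_pseudocounts(p, pos.observations, beta=beta, conditional=cond)
        scores[r] = log_odds(p, bg, scale=scale, min_prob=min_prob)
        percentages[r] = _round_half_away(100.0 * pos.freqs)
    pssm = PSSM(
        query_residues=[p.query_residue for p in profile.positions],
        scores=scores,
        percentages=percentages,
        config={
            "mbw": mbw,
            "beta": beta if pseudocounts else 0.0,
            "pseudocounts": bool(pseudocounts and beta > 0),
            "scale": scale,
            "min_prob": min_prob,
        },
    )
    return profile, pssm


_HEADER_LINE = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded, position-specific sequence weights over per-position blocks"
)
_TRAILER = (
    "\n                      K         Lambda\n"
    "Standard Ungapped    n/a       n/a      (placeholder: Karlin-Altschul "
    "statistics are not computed by this tool)\n"
)


def write_ascii_pssm(pssm: PSSM, path: str | Path, comment: str | None = None) -> None:
    """Write an NCBI-style ASCII PSSM (log-odds table + percentage table)."""
    lines: list[str] = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    lines.append("")
    lines.append(_HEADER_LINE)
    head = "         " + "".join(f"{a:>4}" for a in AA_ORDER) * 2
    lines.append(head)
    for r in range(pssm.n_positions):
        row = f"{r + 1:>5} {pssm.query_residues[r]}  "
        row += "".join(f"{v:>4d}" for v in pssm.scores[r])
        row += "".join(f"{v:>4d}" for v in pssm.percentages[r])
        lines.append(row)
    Path(path).write_text("\n".join(lines) + _TRAILER)


def read_ascii_pssm(path: str | Path) -> PSSM:
    """Minimal reader for files produced by :func:`write_ascii_pssm`."""
    residues: list[str] = []
    scores: list[list[int]] = []
    percentages: list[list[int]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) == 42 and parts[0].isdigit():
            residues.append(parts[1])
            vals = [int(v) for v in parts[2:]]
            scores.append(vals[:20])
            percentages.append(vals[20:])
    if not residues:
        raise ValueError(f"no PSSM data rows found in {path}")
    return PSSM(
        query_residues=residues,
        scores=np.array(scores, dtype=int),
        percentages=np.array(percentages, dtype=int),
    )
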