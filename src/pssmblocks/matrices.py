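"""Background frequencies and BLOSUM62-derived pseudocount conditionals.

Residue order follows the NCBI ASCII PSSM column order.  Background
frequencies are the Robinson & Robinson (1991) estimates used throughout
the BLAST family.  Pseudocount target frequencies are reconstructed from
the BLOSUM62 half-bit log-odds scores s_ab via

    q_ab  proportional to  p_a * p_b * 2^(s_ab / 2)

renormalised to a joint distribution; the conditional q(b|a) = q_ab / p'_a
then drives the classic profile pseudocount g_b = sum_a P_a q(b|a).
Working back from the published integer scores (rather than shipping a
transcribed joint-frequency table) keeps the data path auditable; the
rounding of the scores perturbs the conditionals by a few percent, well
inside the slack the beta mixing parameter already represents.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: NCBI PSSM column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Robinson & Robinson background amino-acid frequencies.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def background_frequencies() -> np.ndarray:
    """Robinson–Robinson backgrounds in PSSM column order, normalised."""
    bg = np.array([_ROBINSON[a] for a in AA_ORDER])
    return bg / bg.sum()


def blosum62_conditional() -> np.ndarray:
    """Matrix C with C[a, b] = q(b | a), rows summing to 1."""
    bg = background_frequencies()
    blosum = substitution_matrices.load("BLOSUM62")
    s = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            s[i, j] = blosum[a][b]
    joint = np.outer(bg, bg) * np.exp2(s / 2.0)
    joint /= joint.sum()
    return joint / joint.sum(axis=1, keepdims=True)
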