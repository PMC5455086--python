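# Methods

## Model

An aligned MSA is a rectangular symbol matrix over the 20 amino acids, the
gap `-`, and the ambiguity codes `X B Z U *`; row 0 is the query/master and
PSSM positions are the query's non-gap columns. Coordinates are 0-based
with inclusive extents internally; 1-based numbering appears only in
human-readable output.

For each query position the pipeline is:

1. **Reduced MSA** — the rows with a residue at the focal column. The query
   always participates; rows absent there contribute nothing to that
   position.
2. **Block** — column interval `[max of reduced-row extent starts, min of
   reduced-row extent ends]`. "Nearest start/end on each side of the focal
   column" reduces to max-of-starts / min-of-ends because every reduced row
   spans the focal column; a brute-force column scan in the test suite
   confirms the equivalence on random alignments.
3. **MBW extension** — blocks narrower than the minimum block width `mbw`
   are widened by `mbw − 1` columns front and rear, clamped to the
   alignment termini; `mbw = 1` is the identity (the unmodified behaviour).
   A width-1 interior block therefore grows to `2·mbw − 1` columns, which
   is the reading we fixed where the informal "becomes MBW" phrasing
   conflicts with the front-and-rear rule; the rule lives in one function
   (`extend_block`) so the alternative is a one-line change.
4. **Sequence weights** — `W_i = Σ_j 1/(r_j·n_aj·l)` over the block. The
   per-column terms sum to `1/l`, so block weights sum to exactly 1; the
   code asserts this rather than renormalising. Gaps inside an extended
   block count as a 21st symbol type for `r_j`/`n_aj`; the focal column has
   no gaps by construction, so the focal distribution stays a distribution
   over residues.
5. **Weighted frequencies** — `P_a = Σ W_i` over rows with focal symbol
   `a`. For a width-1 block this degenerates to `1/r` per observed type,
   which is the pathology the extension removes.
6. **Pseudocounts and scores** — probability mass observed on ambiguity
   symbols is redistributed proportionally over the 20 standard residues
   (over the background when nothing standard was observed), then mixed as
   `(α·P + β·G)/(α+β)` with `α` = (distinct standard residue types at the
   focal column) − 1 and `g_b = Σ_a P_a·q(b|a)`. Positions where the query
   is alone get `α = 0`, i.e. the pure pseudocount prior seeded by the
   query residue. Scores are `round(scale·log2(P/bg))` as half-bit integers
   (scale 2, rounding half away from zero), with `P` floored at 1e−4
   before the log so conserved positions stay finite.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mbw` | 25 | minimum block width, in columns; 1 disables the fix |
| `gap_threshold` | 10 | internal gap-run length (aa) that splits a row when an MSA is preprocessed the way MSA-as-query searches do |
| `beta` | 10 | pseudocount weight; 0 disables pseudocounts |
| `scale` | 2 | half-bit integer score scale |
| `min_prob` | 1e−4 | probability floor before the log-odds |
| `fdr` | 0.1 | false-discovery-rate reference on the pooled ROC |

MBW 25 is the default because intermediate widths (≈13–41) behave almost
identically and 25 sits at the optimum of that plateau in benchmark
comparisons; very small widths (~5) still under-inform the weights.

Backgrounds are the Robinson–Robinson frequencies. Pseudocount
conditionals are derived at import time from the BLOSUM62 half-bit scores
via `q_ab ∝ p_a·p_b·2^(s_ab/2)` (renormalised, then conditioned on the
first residue). Working back from the published integer scores instead of
shipping a transcribed joint-frequency table keeps the data path auditable;
score rounding perturbs the conditionals by a few percent, well inside the
freedom the `beta` knob already represents. Both matrices are plain numpy
arrays and can be overridden by passing `conditional=`/`background` to the
relevant functions.

## Evaluation statistics

TP/FP labels are *inputs* (a third label `ignored` drops a hit from both
counts, as benchmark rule sets do for uncertain homology); computing them
needs a structural gold standard outside this package's scope. The pooled
ROC ranks all hits by E-value and weights each by 1/(its query's total TP
count) — a dataset-wide-constant alternative sits behind a flag. ROC5
filters to E-value < 1, averages the TP counts retrieved before each of
the first five FPs, and normalises by 5T; with fewer than five FPs the
missing terms equal the total TP count retrieved, and queries with no
qualifying TP return a missing value rather than 0. Summaries skip queries
whose only TP is the self-hit. E-value ties rank FP before TP
(pessimistic), then by (query_id, subject_id) for determinism; a property
test checks permutation invariance under that rule.

## Synthetic fixtures

The generators produce the structures that create narrow blocks, not
realistic evolution:

* **gapless** — columns draw a fixed subset of residue types (exact
  per-column diversity) filled with a dominant-residue composition
  (geometric ratio 4; e.g. counts 6/2/1/1 for 10 rows and 4 types). Real
  conserved columns look like this, and it is the regime where the
  width-1 uniform-1/r law distorts most; near-uniform columns would make
  the degenerate distribution accidentally close to the truth and hide the
  pathology.
* **fragmented** — one row replaced by two pieces sharing `overlap`
  columns; overlap 1 collapses the block at the shared column to width 1
  and yields exactly three distinct block extents.
* **hoe** — a two-domain query with domain-A rows over-extending a few
  columns into domain B; the junction blocks are exactly as wide as the
  overhang.
* **hits** — labeled ranked hits whose TP-vs-FP ordering interpolates
  between perfect (quality 1) and inverted (quality 0), E-values distinct
  and < 1.

All randomness flows from one integer seed through one `numpy`
`default_rng`; no global state. What passing tests on these fixtures do
*not* show: behaviour on real alignment column compositions, realistic
gap structure, or full-benchmark-scale effects — the fixtures isolate the
weighting arithmetic and block geometry, nothing more.

## Numerical choices and verification

Production code is floating point; the test oracle re-evaluates the weight
formula in exact rational arithmetic (`fractions.Fraction`) and agrees to
1e−12 on a thousand random small alignments (≤ 8 rows × ≤ 12 columns —
sizes chosen so the exact oracle enumerates instantly), with weight sums
within 1e−9 of 1. Block extents are cross-checked against a literal
first/last-residue column scan. Gapless alignments give byte-identical
PSSMs for every `mbw` (blocks already span everything), and the ASCII
writer/reader round-trips the integer tables.

## Known limitations

* Karlin–Altschul trailer statistics in the ASCII PSSM are placeholders;
  E-value statistics and the search engine itself are out of scope.
* Bit-exact agreement with NCBI-generated ASCII PSSMs is not promised: the
  pseudocount internals of that code differ. The pre-pseudocount weighted
  percentages are pure consequences of the stated formulas and are the
  quantities asserted exactly.
* Stockholm/Clustal input, checkpoint (ASN.1) output and composition-based
  score adjustment are not implemented.
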