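"""Benchmark statistics for ranked homology-search hit lists.

Two statistics are implemented:

* a pooled, weighted ROC curve — hits from all queries are pooled and
  ranked by E-value, and each hit contributes 1/(its query's total TP
  count) to the running TP or FP total, so every query can add at most
  one unit of recall regardless of family size; and
* the per-query ROC5 score, (1/5T) * sum over the first five FPs of the
  TP count retrieved before each, restricted to hits with E-value < 1.0.

TP/FP labels are inputs: assigning them requires a structural gold
standard (e.g. a SCOP/CATH superfamily rule set) that lives outside this
package.  A third label, ``ignored``, excludes a hit from both counts, as
benchmark rule sets do for hits of uncertain homology.

Equal E-values are broken FP-before-TP (pessimistic), then by
(query_id, subject_id) for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

LABELS = ("TP", "FP", "ignored")
_LABEL_TIE_RANK = {"FP": 0, "ignored": 1, "TP": 2}

ROC5_EVALUE_MAX = 1.0


@dataclass(frozen=True)
class RankedHit:
    query_id: str
    subject_id: str
    evalue: float
    label: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def _sort_key(h: RankedHit) -> tuple:
    return (h.evalue, _LABEL_TIE_RANK[h.label], h.query_id, h.subject_id)


@dataclass(frozen=True)
class CurvePoint:
    fp: float
    tp: float


def pooled_roc(
    hits: Iterable[RankedHit],
    tp_per_query: dict[str, int],
    per_query_weighting: bool = True,
) -> list[CurvePoint]:
    """Weighted prefix (FP, TP) points over the pooled E-value ranking.

    With ``per_query_weighting`` each hit carries weight 1/T_q for its own
    query; otherwise a dataset-wide constant 1/(sum of all T_q) is used.
    ``ignored`` hits contribute nothing but retain their rank position.
    """
    ranked = sorted(hits, key=_sort_key)
    for h in ranked:
        if h.query_id not in tp_per_query:
            raise ValueError(f"query {h.query_id!r} missing from tp_per_query")
    total_tp = sum(tp_per_query.values())
    curve: list[CurvePoint] = []
    fp = tp = 0.0
    for h in ranked:
        if h.label == "ignored":
            continue
        w = 1.0 / tp_per_query[h.query_id] if per_query_weighting else 1.0 / total_tp
        if h.label == "TP":
            tp += w
        else:
            fp += w
        curve.append(CurvePoint(fp=fp, tp=tp))
    return curve


def fdr_line(curve: Sequence[CurvePoint], fdr: float = 0.1) -> CurvePoint | None:
    """Last curve point with FP/(FP+TP) <= fdr, or None if no point qualifies."""
    if not (0 < fdr < 1):
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    best = None
    for pt in curve:
        denom = pt.fp + pt.tp
        if denom > 0 and pt.fp / denom <= fdr:
            best = pt
    return best


def roc5(hits_for_one_query: Iterable[RankedHit], n_fp: int = 5) -> float | None:
    """Per-query ROC-n score on hits with E-value < 1.0.

    Ranks by ascending E-value and averages the TP count retrieved before
    each of the first ``n_fp`` FPs, normalised by the total TP count T:
    score = sum(t_i) / (n_fp * T).  When fewer than ``n_fp`` FPs exist the
    remaining terms equal the total TP count retrieved.  Returns None
    (undefined, never 0) when the query has no TP hit below the E-value
    cutoff.
    """
    hits = [h for h in hits_for_one_query if h.evalue < ROC5_EVALUE_MAX]
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"roc5 expects hits from a single query, got {sorted(queries)}")
    total_tp = sum(1 for h in hits if h.label == "TP")
    if total_tp == 0:
        return None
    ranked = sorted(hits, key=_sort_key)
    t_terms: list[int] = []
    tp_seen = 0
    for h in ranked:
        if h.label == "TP":
            tp_seen += 1
        elif h.label == "FP":
            t_terms.append(tp_seen)
            if len(t_terms) == n_fp:
                break
    while len(t_terms) < n_fp:
        t_terms.append(tp_seen)
    return sum(t_terms) / (n_fp * total_tp)


def roc5_by_query(
    hits: Iterable[RankedHit],
    exclude_single_tp: bool = True,
) -> dict[str, float]:
    """ROC5 per query; queries whose only TP is the self-hit are skipped."""
    by_query: dict[str, list[RankedHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, float] = {}
    for q, qhits in by_query.items():
        n_tp = sum(1 for h in qhits if h.label == "TP" and h.evalue < ROC5_EVALUE_MAX)
        if exclude_single_tp and n_tp <= 1:
            continue
        score = roc5(qhits)
        if score is not None:
            out[q] = score
    return out


# -- tabular IO ------------------------------------------------------------

def read_hits_tsv(path: str | Path) -> list[RankedHit]:
    """Read a hits table: query_id, subject_id, evalue, label (TSV, '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"query_id": str, "subject_id": str})
    required = {"query_id", "subject_id", "evalue", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")
    return [
        RankedHit(row.query_id, row.subject_id, float(row.evalue), str(row.label))
        for row in df.itertuples(index=False)
    ]


def write_hits_tsv(hits: Sequence[RankedHit], path: str | Path, header: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "query_id": [h.query_id for h in hits],
            "subject_id": [h.subject_id for h in hits],
            "evalue": [h.evalue for h in hits],
            "label": [h.label for h in hits],
        }
    )
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def tp_counts(hits: Iterable[RankedHit]) -> dict[str, int]:
    """Total TP count per query (no E-value filter), for pooled-ROC weighting."""
    out: dict[str, int] = {}
    for h in hits:
        out.setdefault(h.query_id, 0)
        if h.label == "TP":
            out[h.query_id] += 1
    return out
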