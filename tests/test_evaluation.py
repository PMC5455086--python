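"""Pooled weighted ROC, FDR reference point and per-query ROC5."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pssmblocks import (
    CurvePoint,
    RankedHit,
    fdr_line,
    pooled_roc,
    read_hits_tsv,
    roc5,
    roc5_by_query,
    tp_counts,
    write_hits_tsv,
)


def hits_from_labels(labels, query="q", start_exp=-8):
    """Distinct increasing E-values in the given label order, all < 1."""
    return [
        RankedHit(query, f"s{i}", 10.0 ** (start_exp + 0.5 * i), lab)
        for i, lab in enumerate(labels)
    ]


class TestRankedHit:
    def test_bad_evalue_and_label_rejected(self):
        with pytest.raises(ValueError):
            RankedHit("q", "s", -1.0, "TP")
        with pytest.raises(ValueError):
            RankedHit("q", "s", 1e-3, "TN")


class TestRoc5:
    def test_worked_seven_hit_ranking(self):
        hits = hits_from_labels(["TP", "FP", "TP", "FP", "FP", "FP", "FP"])
        # t = (1, 2, 2, 2, 2), T = 2  ->  9 / 10
        assert roc5(hits) == pytest.approx(0.9)

    def test_perfect_ranking_scores_one(self):
        assert roc5(hits_from_labels(["TP"] * 4 + ["FP"] * 6)) == pytest.approx(1.0)

    def test_five_leading_fps_score_zero(self):
        assert roc5(hits_from_labels(["FP"] * 5 + ["TP"] * 3)) == pytest.approx(0.0)

    def test_fewer_than_five_fps_pads_with_total_retrieved(self):
        # TP,FP,TP: t = (1, 2, 2, 2, 2), T = 2 -> 0.9
        assert roc5(hits_from_labels(["TP", "FP", "TP"])) == pytest.approx(0.9)

    def test_no_tp_returns_missing_not_zero(self):
        assert roc5(hits_from_labels(["FP", "FP"])) is None

    def test_evalue_filter_drops_hits_at_or_above_one(self):
        good = hits_from_labels(["TP", "TP"])
        late_fp = [RankedHit("q", "x", 5.0, "FP")]
        assert roc5(good + late_fp) == pytest.approx(1.0)

    def test_ignored_hits_do_not_count(self):
        hits = hits_from_labels(["TP", "ignored", "FP", "TP", "FP"])
        with_out = roc5(hits)
        without = roc5([h for h in hits if h.label != "ignored"])
        assert with_out == without

    def test_multiple_queries_rejected(self):
        hits = hits_from_labels(["TP"]) + hits_from_labels(["TP"], query="q2")
        with pytest.raises(ValueError):
            roc5(hits)

    def test_invariant_to_monotone_evalue_rescaling(self):
        labels = ["TP", "FP", "FP", "TP", "FP", "TP", "FP", "FP", "FP"]
        a = roc5(hits_from_labels(labels))
        b = roc5([RankedHit(h.query_id, h.subject_id, h.evalue ** 0.3, h.label)
                  for h in hits_from_labels(labels)])
        assert a == b

    def test_single_tp_queries_excluded_from_summary(self):
        hits = hits_from_labels(["TP", "FP"]) + hits_from_labels(
            ["TP", "TP", "FP"], query="q2"
        )
        scores = roc5_by_query(hits)
        assert set(scores) == {"q2"}


class TestPooledRoc:
    def test_single_query_full_recall_no_fps(self):
        hits = hits_from_labels(["TP", "TP"])
        curve = pooled_roc(hits, {"q": 2})
        assert curve[-1] == CurvePoint(fp=0.0, tp=pytest.approx(1.0))

    def test_per_query_weighting(self):
        hits = [RankedHit("a", "s1", 1e-8, "TP"), RankedHit("b", "s1", 1e-7, "TP")]
        curve = pooled_roc(hits, {"a": 1, "b": 2})
        assert curve[-1].tp == pytest.approx(1.0 + 0.5)

    def test_dataset_constant_weighting_flag(self):
        hits = [RankedHit("a", "s1", 1e-8, "TP"), RankedHit("b", "s1", 1e-7, "TP")]
        curve = pooled_roc(hits, {"a": 1, "b": 2}, per_query_weighting=False)
        assert curve[-1].tp == pytest.approx(2 / 3)

    def test_ignored_hits_contribute_nothing(self):
        hits = [RankedHit("q", f"s{i}", 10.0 ** (-6 + i), "ignored") for i in range(4)]
        assert pooled_roc(hits, {"q": 1}) == []

    def test_unknown_query_rejected(self):
        with pytest.raises(ValueError):
            pooled_roc([RankedHit("mystery", "s", 1e-5, "TP")], {"q": 1})

    def test_coordinates_non_decreasing(self):
        hits = hits_from_labels(["TP", "FP", "TP", "FP", "FP", "TP"])
        curve = pooled_roc(hits, {"q": 3})
        for p0, p1 in zip(curve, curve[1:]):
            assert p1.fp >= p0.fp and p1.tp >= p0.tp

    def test_all_queries_full_recall_sums_to_query_count(self):
        hits = []
        for q in ("a", "b", "c"):
            hits += hits_from_labels(["TP", "TP", "FP"], query=q)
        curve = pooled_roc(hits, tp_counts(hits))
        assert curve[-1].tp == pytest.approx(3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["TP", "FP"]), min_size=2, max_size=6))
    def test_equal_evalue_ties_resolve_fp_first(self, labels):
        # all hits share one E-value; any input permutation must give the
        # same curve as the explicit FP-before-TP ordering
        base = [RankedHit("q", f"s{i}", 1e-3, lab) for i, lab in enumerate(labels)]
        expected = pooled_roc(sorted(base, key=lambda h: h.label == "TP"), {"q": 9})
        for perm in itertools.islice(itertools.permutations(base), 24):
            assert pooled_roc(list(perm), {"q": 9}) == expected


class TestFdrLine:
    def test_no_fps_returns_final_point(self):
        curve = pooled_roc(hits_from_labels(["TP", "TP"]), {"q": 2})
        assert fdr_line(curve, 0.1) == curve[-1]

    def test_first_hit_fp_yields_missing(self):
        curve = pooled_roc(hits_from_labels(["FP"]), {"q": 1})
        assert fdr_line(curve, 0.1) is None

    def test_alternating_hits_at_half_fdr(self):
        labels = ["TP", "FP"] * 4
        curve = pooled_roc(hits_from_labels(labels), {"q": 4})
        pt = fdr_line(curve, 0.5)
        # direct-scan oracle: last point with FP <= TP
        expected = [p for p in curve if p.fp <= p.tp][-1]
        assert pt == expected

    def test_bad_fdr_rejected(self):
        with pytest.raises(ValueError):
            fdr_line([], 1.5)


class TestHitsTsv:
    def test_round_trip(self, tmp_path):
        hits = hits_from_labels(["TP", "FP", "ignored"])
        path = tmp_path / "hits.tsv"
        write_hits_tsv(hits, path, header="demo run")
        assert path.read_text().startswith("# demo run")
        assert read_hits_tsv(path) == hits

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("query_id\tsubject_id\tevalue\nq\ts\t0.5\n")
        with pytest.raises(ValueError, match="label"):
            read_hits_tsv(path)
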