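"""Pooled weighted ROC and per-query ROC5 on synthetic labeled hit lists.

Generates two hit lists of different ranking quality, then computes the
pooled E-value-ranked ROC curve (each hit weighted by 1/(its query's TP
total)), the weighted TP count at 10% FDR, and per-query ROC5 scores.
"""

from pssmblocks import fdr_line, make_ranked_hits, pooled_roc, roc5_by_query, tp_counts

for quality in (0.9, 0.5):
    hits = make_ranked_hits(n_queries=20, tps_per_query=8, fps_per_query=12,
                            ranking_quality=quality, seed=11)
    counts = tp_counts(hits)
    curve = pooled_roc(hits, counts)
    at_fdr = fdr_line(curve, fdr=0.1)
    scores = roc5_by_query(hits)
    mean_roc5 = sum(scores.values()) / len(scores)
    print(f"ranking quality {quality}:")
    print(f"  weighted TP total        : {curve[-1].tp:.2f} "
          f"(= {len(counts)} queries at full recall)")
    tp_at = f"{at_fdr.tp:.2f}" if at_fdr else "n/a"
    print(f"  weighted TP count @10%FDR: {tp_at}")
    print(f"  mean ROC5 over {len(scores)} queries: {mean_roc5:.3f}")

print()
print("Higher ranking quality places TPs above FPs, so more weighted TPs are")
print("retrieved before the 10% false-discovery threshold and ROC5 rises")
print("toward 1; ROC5 = 1 means every TP outranks the first five FPs.")
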