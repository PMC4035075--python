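"""Evaluate a predictor against validated interactions.

Generates a small study, scans it, then computes confusion counts, the
precision/recall threshold sweep, the optimal score (where precision and
recall intersect) and the ROC AUC against decoy negatives.
"""

from mirduplex import (
    StudyConfig,
    generate_study,
    predict_transcriptome,
    confusion_from_predictions,
    precision_recall,
    threshold_sweep,
    optimal_score,
    roc_auc,
)

study = generate_study(StudyConfig(n_tp=20, n_fn=20, n_decoys=5, seed=4))
validated = [r.pair for r in study.interactions]

scan = predict_transcriptome(study.mirnas, study.all_transcripts, cutoff=6.0)
preds = list(scan.predictions)
counts = confusion_from_predictions(preds, validated, study.negatives)
prec, rec = precision_recall(counts)
print(f"TP {counts.tp}  FP {counts.fp}  FN {counts.fn}  TN {counts.tn}")
print(f"precision {prec:.3f}  recall {rec:.3f}")

curve = threshold_sweep(preds, validated, study.negatives)
print(f"optimal score (precision/recall crossing): {optimal_score(curve)}")

# ROC: best penalty per validated pair vs per negative pair (missed = sentinel)
best = {}
for p in preds:
    best[p.pair] = min(p.score, best.get(p.pair, float("inf")))
sentinel = max(p.score for p in preds) + 1
pos = [best.get(pair, sentinel) for pair in validated]
neg = [best.get(pair, sentinel) for pair in study.negatives]
_, auc = roc_auc(pos, neg)
print(f"AUC {auc:.3f}")
# Recall below 1 reflects the heavy-edit ("FN-like") half of the study,
# which the scanner is expected to miss at this cutoff.
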