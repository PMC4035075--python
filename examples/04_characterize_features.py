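"""Compare duplex features between recovered and missed interactions.

Computes the four per-interaction features (miRNA GC, longest match run,
first match stretch, match/mismatch ratio) for the near-perfect vs the
heavy-edit group, tests each with a Wilcoxon rank-sum, and prints the
positional entropy profile of each group.
"""

from mirduplex import StudyConfig, generate_study, compare_feature_distributions
from mirduplex.interaction_features import entropy_profile, feature_vector

study = generate_study(StudyConfig(n_tp=50, n_fn=50, n_decoys=0, seed=2))
mirna_seq = {m.identifier: m.residues for m in study.mirnas}

def collect(records):
    vals = {"gc_fraction": [], "max_match_stretch": [], "first_stretch": [],
            "match_mismatch_ratio": []}
    for r in records:
        fv = feature_vector(study.alignments[r.pair], mirna_seq[r.mirna_id])
        for k in vals:
            vals[k].append(getattr(fv, k))
    return vals

tp, fn = collect(study.validated), collect(study.divergent)
for feat in tp:
    p = compare_feature_distributions(tp[feat], fn[feat]).pvalue
    print(f"{feat:22s} rank-sum p = {p:.3g}")

tp_entropy = entropy_profile([study.alignments[r.pair] for r in study.validated])
fn_entropy = entropy_profile([study.alignments[r.pair] for r in study.divergent])
print("mean entropy (bits): "
      f"TP-like {sum(tp_entropy.values)/20:.3f}  FN-like {sum(fn_entropy.values)/20:.3f}")
# Duplex-geometry features separate the groups sharply; GC content, shared
# by construction, does not.  FN-like duplexes carry higher positional
# entropy because their edits are scattered across the alignment.
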