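# mirduplex

Plant miRNA target-site duplex alignment and benchmark-evaluation toolkit.

Plant miRNAs silence messenger RNAs through near-perfect complementarity, and
computational target predictors score candidate sites with an additive
penalty over the miRNA:mRNA duplex — mismatches and bulges cost more than
G:U wobbles, and edits in the 5′ seed region cost double. Benchmarking such
predictors against experimentally validated interactions requires a fair,
reproducible evaluation harness: confusion bookkeeping, precision/recall
threshold optimization, ROC analysis, predictor combination, and a feature
suite that explains *why* some validated interactions are systematically
missed. `mirduplex` packages that entire machinery as an importable library
(plus a thin `mirduplex` CLI), together with a ground-truth synthetic-study
generator so every stage can be exercised and tested without any external
predictor or database.

## What it computes

For a duplex alignment with per-position states M (Watson–Crick match),
W (G:U wobble), X (mismatch), G (gap/bulge):

- **Penalty**: `Σᵢ cᵢ·wᵢ` with `c(M)=0, c(W)=0.5, c(X)=c(G)=1` and
  `wᵢ = 2` for positions *i* in the seed window (default 2–13 from the
  miRNA 5′ end), else 1. A bounded dynamic program (≤ 3 gaps) finds the
  minimum-penalty global alignment, ties broken toward fewer, more 3′ gaps.
- **Evaluation**: precision = TP/(TP+FP), recall = TP/(TP+FN),
  specificity = TN/(TN+FP); a threshold sweep over the predictor's native
  score grid; the **optimal score** at the precision/recall intersection;
  trapezoid ROC **AUC** (equal to the pairwise concordance probability, ties
  ½); union/intersection combination of predictors.
- **Features**: miRNA GC fraction; the longest run of continuous matches;
  the first stretch of matches from the first matched base; the
  match/mismatch ratio (#M / (#X + #G), wobbles in neither term); positional
  Shannon entropy `Hₙ = −Σ p(s) log₂ p(s)` over the three-state taxonomy
  {M, W, X∪G}; the +1/−1/+0.5 alignment-vector encoding of the first 20
  positions with complete-linkage hierarchical clustering; Wilcoxon rank-sum
  comparisons between interaction groups; and a lowess trend of duplex ΔG
  against transcript length with Spearman ρ.
- **Synthetic studies**: near-perfect ("TP-like") vs heavy-edit ("FN-like")
  implanted target sites — the latter instantiating the seed-window edit
  categories of two mismatches + one wobble, or three mismatches — plus
  decoy transcripts with no alignable site, and a ΔG table drawn as
  `slope·length + noise`, all exactly labelled and seed-reproducible.

## Worked example

```sh
python examples/06_full_pipeline.py
```

prints (seed 42):

```
strict   cutoff 3.0: precision 1.00, recall 0.50, optimal score 3.0, AUC 0.75
lenient  cutoff 6.0: precision 0.94, recall 0.53, optimal score 6.0, AUC 0.77
strict|lenient|union: TP 16, FP 1
strict|lenient|intersection: TP 15, FP 0
first_stretch rank-sum p = 1.86e-06
gc_fraction   rank-sum p = 0.42
energy trend rho = -0.81
```

The strict predictor recovers every near-perfect site with no false
positives but misses the heavy-edit half of the validated set — recall 0.50
is exactly the designed fraction of divergent duplexes. The union raises
true-positive coverage; the intersection removes the false positive. The
rank tests show the signature this package is built to expose: duplex
geometry (first stretch of matches) separates recovered from missed
interactions decisively, while miRNA GC content does not. The energy trend
recovers the built-in negative ΔG-vs-length slope.

The other scripts in `examples/` each demonstrate one capability: duplex
alignment, transcript scanning, predictor evaluation, feature
characterization, and the energy trend.

## Command line

```
mirduplex simulate|scan|evaluate|combine|features|trend|run
```

Each subcommand is a thin wrapper over the library; `mirduplex run`
executes the full pipeline from a TOML configuration and writes a JSON
report that validates against the packaged schema.
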