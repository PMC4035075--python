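# Methods

## Duplex model

A miRNA:mRNA target-site duplex is modelled as a global, antiparallel
alignment of the miRNA (5′→3′) against a candidate transcript window.
Every aligned column is one of four states: Watson–Crick match (M), G:U
wobble (W), mismatch (X), or gap/bulge (G). G:U pairs are thermodynamically
tolerated but weaker than Watson–Crick pairs, so they carry an intermediate
cost throughout the package — 0.5 against 1 for a mismatch or gap — and the
same three-way taxonomy {M, W, X∪G} is reused by the entropy profile and
the heatmap-style alignment vectors (+1 / +0.5 / −1) so that a single state
classification underlies every feature.

The penalty of an alignment is the sum of per-column costs, with columns in
a positional *seed window* multiplied by 2. Defaults:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| mismatch, gap    | 1.0     | per-column cost                                |
| wobble           | 0.5     | per-column cost of a G:U pair                  |
| seed window      | 2–13    | miRNA positions (1-based, 5′ end) doubled      |
| seed multiplier  | 2.0     | weight inside the window                       |
| max gaps         | 3       | gap columns explored per duplex                |

These are the conventional plant-predictor scoring family; all are
configurable per `PenaltyScheme` because published tools differ in their
exact gap costs and windows. Positions are column indices, which coincide
with miRNA positions for gap-free alignments; the dynamic program tracks the
column index exactly (after *i* miRNA bases, *j* site bases and *g* gap
columns, the emitted column count is (i+j+g)/2), so the reported penalty
always equals the scoring function applied to the reported state string.

The aligner is a bounded global dynamic program over (miRNA prefix, reversed
site prefix, gap count). Ties are resolved deterministically: fewer gaps
first, then gaps pushed toward the miRNA 3′ end (backtracking from the
alignment end prefers gap moves, which places gap columns at the largest
possible indices); between the two gap orientations at one column, the
transcript-bulge move is preferred. Plant duplex bulges are empirically
3′-biased, and determinism matters more here than the specific convention.
Equality of the DP minimum with exhaustive enumeration over all gap
placements is asserted in the tests for short sequences.

The miRNA is never truncated; candidate windows are chosen so terminal
unpaired transcript bases fall outside the reported site. Coordinates are
1-based inclusive transcript positions everywhere.

## Reference scanner

The scanner slides each miRNA over each transcript and reports, per cluster
of transitively overlapping candidate sites, the single lowest-penalty site
(ties: leftmost) with penalty ≤ cutoff. Candidate generation is
seed-anchored: a full alignment is attempted only where the transcript
contains the reverse complement of miRNA positions 2–8 with at most one
mismatch, and — as a second, heuristic screen — only where the canonical
gap-free window costs at most `cutoff + gap_rescue_margin` (default 8).
The margin bounds how much penalty gap moves are assumed able to recover;
it is a speed/completeness trade-off, not an exact bound, which is why an
exhaustive mode (every window, every permitted length, no screens) is kept
and used as the oracle in tests. Monotonicity in the cutoff and recovery of
every implanted site whose realized penalty fits the cutoff are asserted
against ground truth.

The scanner is deliberately *not* a re-implementation of any published
tool: it exists so the evaluation machinery can be driven end-to-end by a
predictor whose behaviour is exactly known.

## Evaluation

Matching between predictions and validated interactions is pair-level
(miRNA id, target id) and site-agnostic, because curated validated sets
carry no site coordinates. Precision is defined as 1.0 on an empty call set
(vacuous; recall is 0 there, so the optimal-score search is unaffected).
Score orientation is explicit (`lower_better` penalties vs `higher_better`
expectation scores) rather than sign-flipped.

Threshold sweeps use the predictor's native grid of unique scores. The
optimal score is the grid threshold minimizing |precision − recall|, ties
broken toward larger precision + recall, then the smaller threshold — the
discrete analogue of the precision/recall intersection. ROC curves are
computed over all score thresholds with the trapezoid AUC; per-pair scores
for ROC use each pair's best prediction and a worse-than-anything sentinel
for pairs never called, which treats "not predicted" as the weakest possible
call. Union combination keeps the better score per pair, intersection the
worse.

The ΔG-vs-length trend uses statsmodels lowess (default span 0.5) plus the
Spearman rank correlation; degenerate inputs (constant ΔG or length) report
ρ = 0 rather than NaN.

## Synthetic studies

The generator emulates the contrast between interactions predictors recover
and interactions they miss. Each interaction gets one miRNA (default
21 nt), one transcript (length uniform on 300–1500 nt), and one implanted
site. TP-like profiles draw 0–1 seed-window G:U wobbles and 0–1 mismatch in
the 3′ region; FN-like profiles instantiate the heavy seed-edit categories —
two mismatches plus one wobble, or three mismatches — in the positional
seed window 2–12, plus two mismatch/gap/wobble edits in the 3′ region. Both
groups share the miRNA generator and its GC target (default 0.5), so duplex
geometry differs between groups while base composition does not; this is
the designed null for the GC rank test. Every implanted site is re-aligned
and the realized state counts must reproduce the requested profile exactly
(edit placements are resampled on failure), so ground-truth labels are
exact, not approximate.

Energy records are drawn as ΔG = slope·length + N(0, σ), slope
−0.05 kcal/mol/nt and σ = 10 kcal/mol by default, giving a strong but noisy
negative trend over the transcript-length range.

Decoy transcripts (negatives for TN/ROC) are rejection-sampled: a candidate
is kept only if its best gap-free window penalty against every study miRNA
exceeds a guard (default 6) *and* the seed-anchored scanner finds nothing at
the guard cutoff. The gap-free screen is a fast vectorized scan; the
scanner pass guarantees the negatives are clean with respect to the
predictor actually used in the pipeline.

All randomness flows from one integer seed through a single generator;
identical configurations produce byte-identical FASTA/TSV outputs.

What the generator does **not** emulate: real miRNA family structure and
conservation, multi-site targets, target-site accessibility, degradome
evidence, and real free-energy computation (ΔG values are consumed as
inputs, drawn from the linear model above). Passing tests therefore show
that the machinery measures what it claims on data with known structure —
not that any particular predictor performs well on real transcriptomes.

## Numerical and design choices

- The Shannon entropy profile uses the three-state taxonomy {M, W, X∪G}
  and log base 2, the same merge the alignment-vector encoding uses; each
  alignment is truncated or padded to 20 positions, padding with the
  mismatch/gap class (absence of pairing is non-complementarity).
- Both stretch features treat wobbles as run-breaking ("continuous
  matches" means M only); the first stretch starts at the first matched
  base, so leading non-matches are skipped and an alignment without any
  match scores 0. The match/mismatch ratio is ∞ when there are no
  mismatches or gaps; rank tests handle the infinity by rank.
- Clustering of alignment vectors is complete-linkage over Euclidean
  distances via scipy; merge heights are checked against a brute-force
  agglomerative oracle in tests.
- Group comparisons use the two-sided Wilcoxon rank-sum test (scipy
  `ranksums`).
- Floating-point comparisons in the aligner and scanner use a 1e-9
  tolerance for penalty equality at cutoffs.
- Curated-table bookkeeping: interaction deduplication is pair-level
  (idempotent, first occurrence kept); the ambiguous-miRNA filter matches
  family names after stripping species prefixes (`ath-`, `osa-`) and
  mature-arm suffixes (`-5p`/`-3p`) but keeps lettered variants distinct.
  The bundled curated tables are a deterministic **synthetic stand-in**
  (`synthetic_curated_tables`) with the published structure — 330
  Arabidopsis pairs, 134 non-Arabidopsis of which the miR414/miR413
  families account for 19, leaving 115 after filtering — used to exercise
  the real parsing/dedup/filter path; a workbook converter
  (`convert_curated_workbook`) ingests the real spreadsheet when available.
- Problem sizes: the demo pipeline evaluates scanning on a 25+25
  interaction subset with 8 decoys while feature characterization uses the
  full study; the characterization studies use 100 + 100 interactions. The
  acceptance script runs the aligner-oracle comparison at 500 random pairs
  (length ≤ 10, ≤ 2 gaps), evaluation identities at 100 random confusion
  tables and 50 score sets, optimal-score recovery at 100 constructed
  curves, and entropy bounds at 1,000 random columns.

## Known limitations

- The seed-anchored scanner can miss sites whose seed region carries more
  edits than the anchor tolerates; this is intentional (it is exactly the
  false-negative behaviour the feature suite characterizes) but means
  anchored-mode recall is a property of the anchor settings.
- The gap-rescue margin is heuristic; pathological sequences could in
  principle hide a low-penalty gapped site behind an expensive gap-free
  canonical window. Exhaustive mode is available where completeness
  matters.
- Pair-level TP matching cannot distinguish a correct pair predicted at the
  wrong site.
- The aligner explores at most 3 gap columns; duplexes needing larger
  asymmetric bulges are reported as unalignable.
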