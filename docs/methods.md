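# Methods

`motifgrammar` asks whether the cell type in which a transcription factor
(TF) binding site is active can be predicted from the *combination of DNA
motifs* present in a fixed window around the ChIP-seq peak centre, and
whether that predictive structure can be read back out as a small set of
interpretable rules — a motif grammar.  This note records the models,
conventions, parameter choices and known limitations of each stage.

## 1. Peak windows

Peaks are read from ENCODE narrowPeak (BED6+4) or plain BED; all
coordinates are 0-based half-open.  For each cell type the strongest
`top_n_peaks` (default 500) *unique* peaks by −log10 p are kept: duplicate
intervals collapse to their best-scoring record, and ranking ties break by
signal value, then (chrom, start), so selection is deterministic.  The peak
centre is the narrowPeak summit when one is recorded, else the floor of the
interval midpoint — the summit is the best single-base estimate of the
binding position and flooring makes midpoints deterministic.  Windows are
`[centre − flank, centre + flank)` with `flank = 120` by default (240 bp
windows, the operating point selected by the window-size sweep below).
Windows that would cross a contig boundary are dropped, not clipped: the
classifier assumes feature vectors from equal-length sequence, and a
partial window would bias its counts downward.  Soft-masked (lowercase)
genome sequence is uppercased and scanned normally.

## 2. Motif database and scanning

Motifs are position probability matrices (PPMs) in HOMER motif format
(`>CONSENSUS<TAB>NAME<TAB>THRESHOLD` followed by one probability row per
position).  Rows summing within [0.99, 1.01] are renormalised; anything
further off is rejected as malformed.  Duplicate names get `_2`, `_3`, …
suffixes because motif names become feature-matrix columns.

Scoring is natural-log log-odds against a background base distribution
(uniform by default) with pseudocount 10⁻³:

    S(x, o, ±) = Σ_i log( (p_i[b_i] + c) / (1 + 4c) / q[b_i] )

where `b_i` is the base read at offset `o + i` (on the − strand, of the
reverse-complemented window).  An *occurrence* is any (offset, strand) pair
with `S ≥ detection_threshold`.  Conventions, fixed once and documented so
palindromes and overlaps are reasoned about consistently:

* both strands are scanned; a palindrome matching both strands at one
  offset counts twice;
* overlapping hits all count (no greedy masking);
* a window containing `N` can never be a hit (score −∞) — we do not
  fabricate scores for unknown bases;
* threshold comparison is `≥`;
* a header with no threshold defaults to 0.8 × the maximum achievable
  score, a common hit-calling fraction when no calibrated cut-off exists
  (logged so users can override).

The count matrix (samples × motifs, nonnegative integers, with cell-type
labels) is the interchange object between scanning and modelling, stored
as TSV.

## 3. Random forest

The classifier is a classical bagged decision forest: 500 trees (the
default; OOB error is flat well before 500 on these data), each grown on a
bootstrap sample of size n, each split chosen by Gini impurity over a
fresh random subset of `features_per_split` features
(`floor(sqrt(p))` by default), trees grown to purity with minimum node
size 1, majority-vote aggregation.  The trainer is implemented in-package
with a numba-compiled histogram splitter specialised to small-integer
count features: each feature is mapped once to dense codes of its sorted
unique values, so one class-histogram pass per node evaluates every
possible threshold.  This design was chosen because downstream stages need
what library forests hide — per-tree bootstrap/OOB index sets and walkable
split paths — and because histogramming integer counts is roughly an order
of magnitude faster than generic sorted splitting, which is what makes the
repeated cross-validations below practical on one CPU.  Split thresholds
are midpoints between adjacent observed values in the node, so a split on
a count feature always falls strictly between two attainable counts.

Numerical conventions: splits require a strictly positive impurity
decrease (> 10⁻¹⁰), otherwise the node becomes a leaf (relevant when
duplicate rows carry different labels); vote and leaf ties resolve to the
first class in sorted order, making every prediction deterministic;
`sklearn`'s forest is used in the test suite as an independent accuracy
cross-check, never as the implementation.

**OOB error.**  Each sample is predicted by majority vote of only the
trees that did not draw it into their bootstrap; the error is the
misclassified fraction among samples with ≥ 1 OOB tree.

**Importance (MDA).**  Permutation mean decrease accuracy: for each tree
and each feature used by that tree, the feature's values are permuted
among that tree's OOB samples and the OOB accuracy drop recorded; raw MDA
is the mean drop over all trees (trees not using the feature contribute
exactly 0, since permuting an untested feature cannot change a
prediction — the implementation exploits this, and re-walks only samples
whose baseline decision path tested the permuted feature).  Reported
*scaled MDA* divides the raw MDAs by their standard deviation across all
features (ddof = 1, the R `sd()` convention this scaling convention comes
from).  If that sd is 0 the scaled values are reported as 0 with a
warning.  The conventional reporting shortlist is scaled MDA > 6.  Note
that MDA is sometimes loosely described as the error increase "caused by
removing" a variable; what is computed here (and by the reference R
implementation) is the permutation definition.

**Two-round training.**  Round 1 trains with the default
`features_per_split` and removes every feature with negative raw MDA
(irrelevant features whose inclusion hurts accuracy).  Round 2 tunes
`features_per_split` on the reduced matrix over the 3-point grid
{max(1, ⌊m/2⌋), m, min(p, 2m)}, m = ⌊√p⌋ — mirroring the stepFactor-2
exploration of the usual `tuneRF` heuristic — keeping the value with the
smallest OOB error (ties to the smaller value: simpler trees).  The tuned
forest is returned together with its importance table; callers that only
need predictions (cross-validation) can skip the final importance
computation, which does not alter the model.

## 4. Evaluation

**Cross-validation.**  10 repeats of stratified 10-fold CV (stratified
because balanced folds stabilise per-class metrics; the repeat seed is
`seed + r`).  The *entire* two-round procedure — including MDA-based
feature removal — runs inside each training fold, so no importance
information leaks from held-out samples.  Held-out vote fractions are
pooled within a repeat; metrics are computed on the pool and averaged
(± sd) over repeats.

**AUROC.**  The fraction of trees voting for a class is the score of a
one-vs-rest binary classifier; the AUROC is computed rank-based (the
normalised Mann–Whitney U, ties counting ½), which is exactly the
pairwise-comparison definition.

**F1.**  Per class, one-vs-rest: `F1 = 2·precision·recall /
(precision + recall)`, defined as 0 when both are 0 (e.g. a class never
predicted).

**Window-size sweep.**  For each candidate flank the windows are rebuilt,
rescanned and cross-validated; the recommended flank maximises mean
per-class F1, ties to the smaller flank (smaller windows are cheaper and
less confounded).  The sweep defaults to 2 repeats × 5 folds per flank
rather than the full 10 × 10: the sweep is a coarse argmax over a grid,
and 10 pooled folds per flank already separate the candidates by far more
than their repeat-to-repeat spread.

## 5. Rule mining

Every root-to-leaf path of every tree is a candidate rule — a conjunction
of integer threshold conditions on motif counts.  Because counts are
integers, thresholds are integerised at extraction: `x ≤ 2.5` → `x ≤ 2`,
`x > 2.5` → `x ≥ 3`; an upper bound of 0 renders as `MOTIF=0`.  Paths are
truncated at 6 conditions (deep-path rules are low-frequency and would be
filtered anyway; the cap is configurable); multiple bounds on one motif
merge to the tightest interval, and an empty interval marks the rule
unsatisfiable (frequency 0, removed by the filter).  Duplicated condition
sets are extracted once.

* **Metrics**: frequency = fraction of training samples satisfying all
  conditions; outcome = majority class among them (ties alphabetical);
  error = non-outcome fraction among them.  Outcomes are re-derived from
  the data rather than taken from the leaf, which makes deduplication
  well-defined.
* **Pruning**: conditions visited last-to-first; a condition is removed
  when the relative error decay `(E′ − E)/max(E, 10⁻⁶)` is ≤ 0.05 (the
  usual default for this style of rule post-processing); rules never
  shrink below one condition.
* **Selection**: a deterministic greedy rule-list construction replaces
  regularised-forest-based selection: candidates sorted by (error, length,
  −frequency, condition string) are appended iff they strictly reduce the
  training misclassification of the first-match-wins rule list whose
  default prediction is the global majority class; passes repeat until no
  addition.  This keeps the stated goal — a relevant, non-redundant,
  predictive subset — while being reproducible and dependency-free.  One
  structural consequence: rules predicting the default class can never
  strictly improve the list, so with balanced classes the alphabetically
  first class typically ends with no rule — mirroring the "No rule
  identified" classes seen in practice.
* **Filtering**: keep rules with frequency ≥ 0.08 and error ≤ 0.7
  (boundary values survive; "below"/"above" are read strictly).

## 6. Synthetic data with planted grammars

The generator makes the whole pipeline testable without downloads.  A
`GrammarSpec` defines classes by requirement clauses (motif, minimum
count), optional exclusions, and a shared decoy set.  Each sample is an
i.i.d. background contig (uniform base frequencies by default, length 620
so that flanks up to 300 bp can be swept) with a 240 bp window at its
centre; a matching narrowPeak record with the summit at the contig centre
is emitted so the peak-processing stages run exactly as on real data.

* Required motifs are planted `min_count + surplus` times, surplus ∈
  {0, 1}, at uniform non-overlapping positions within ±100 bp of the
  centre; instances are *sampled from the PWM* (re-sampled until they pass
  the detection threshold), so counts are noisy but the clause holds by
  construction, and the tight surplus keeps recovered rule thresholds
  testable to ±1.
* Decoys are planted in every class at rate `lambda_bg` per window
  (default 0.1; instances land anywhere on the contig, with the contig
  rate scaled so the *window* sees `lambda_bg` in expectation).  The rate
  was chosen so the expected planted footprint (~44 decoys × 8 bp × 0.1 ≈
  35 bp) stays well below window capacity and non-overlapping placement
  always succeeds.
* The matched null runs the identical process with the class clauses
  ignored — every motif becomes a decoy — so labels carry no signal while
  every count column keeps a live distribution; it calibrates chance-level
  AUROC and the scaled-MDA threshold.

The default benchmark is 5 classes × 300 windows over a 50-motif database
(width 8, concentration 50, i.e. near-consensus PWMs): classes 1–4 each
require ≥ 3 copies of their own motif, class 5 requires one copy each of
two motifs (the conjunctive case), and the remaining 44 motifs are decoys.

What the synthetic data does *not* emulate: genomic base composition and
repeats, correlated motif co-occurrence in background, spatial
motif-pair arrangement, read-level noise or peak-calling artefacts.
Passing the planted benchmark therefore shows the machinery is correct and
calibrated, not that any particular biological dataset will yield a clean
grammar.

## 7. Determinism and problem sizes

A single master seed drives simulation, bootstraps, feature subsets,
permutations and fold assignments; all derived seeds are drawn once from a
`RandomState(seed)` stream, and repeated runs produce byte-identical
TSV/JSON outputs (output headers carry the tool version and a hash of the
analysis parameters, excluding the output path).  The shipped checks run
the benchmark at its native size (1 500 windows × 50 motifs, 10×10 CV for
signal and null) and the bookkeeping check at full scale (3 000 windows ×
2 067 motifs); the sweep uses 2 × 5 CV per flank as discussed above.

## 8. Known limitations

* Rules use occurrence counts only; motif order, spacing and strand
  arrangement are out of scope.
* The greedy rule-list selection is order-dependent by design; a
  different, equally predictive rule set may exist.
* HOMER thresholds from third-party files are taken at face value; the
  scanner's background/pseudocount conventions are close to, but not
  bit-identical with, other scanners.
* Classes smaller than the fold count cannot be cross-validated, and
  classes with < 2 samples cannot be trained on.
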