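# motifgrammar

Cell-type specific DNA motif grammar discovery from TF ChIP-seq peaks.

Many transcription factors (TFs) bind the same core DNA motif yet occupy
different genomic loci in different cell types, presumably because binding
requires co-binding partners that vary by cell type.  If so, the binding
sites of one TF should carry *different combinations of partner motifs* —
a motif grammar — in each cell type.  `motifgrammar` tests this hypothesis
and extracts the grammar:

1. **Windows** — for each cell type, take the strongest unique ChIP-seq
   peaks (default 500 by −log10 p) and extract fixed 240 bp windows around
   the peak centres (summit if recorded, else interval midpoint).
2. **Annotation** — count occurrences of every motif in a PWM database
   (HOMER motif format) in every window: log-odds scoring against a
   background model, both strands, all offsets, hits at or above each
   motif's detection threshold.
3. **Classification** — train a 500-tree random forest to predict the
   cell type from the motif-count vector, in two rounds: features with
   negative permutation importance (mean decrease accuracy, MDA) are
   dropped, then the per-split feature count is tuned by out-of-bag (OOB)
   error.  Performance is measured by repeated stratified 10×10
   cross-validation, with one-vs-rest AUROC computed from the fraction of
   trees voting for each class, and per-class
   F1 = 2·precision·recall/(precision+recall).
4. **Grammar** — mine the forest for interpretable rules: every
   root-to-leaf path is a candidate conjunction of integer motif-count
   conditions (e.g. `NFE2>=3`), which is measured (frequency, error),
   pruned, reduced to a compact non-redundant rule list, and filtered
   (frequency ≥ 8 %, error ≤ 0.7).  The surviving rules per cell type are
   the motif grammar.

A synthetic-data generator with *planted* grammars (class-specific motif
requirements over an i.i.d. background, plus a matched null) makes every
stage testable end-to-end without genome downloads; see
[`docs/methods.md`](docs/methods.md) for the models, conventions and
parameter choices.

## Worked example

Simulate the default planted benchmark (5 cell types × 50 windows here to
keep it quick; classes `cell1..cell4` each require ≥ 3 copies of their own
motif, `cell5` requires one copy each of two motifs) and run the full
pipeline on it:

```sh
motifgrammar simulate --out sim --seed 5 --n-per-class 50
motifgrammar run --out results --seed 5 --repeats 2 --folds 5 --top-n 50 \
    --genome sim/genome.fasta --motifs sim/motifs.homer \
    --peaks cell1=sim/peaks_cell1.narrowPeak --peaks cell2=sim/peaks_cell2.narrowPeak \
    --peaks cell3=sim/peaks_cell3.narrowPeak --peaks cell4=sim/peaks_cell4.narrowPeak \
    --peaks cell5=sim/peaks_cell5.narrowPeak
cat results/grammar.txt
```

which prints the recovered grammar:

```
# motifgrammar v0.1.0 config=80cd72632ef0
No rule identified -> cell1
M02>=2 -> cell2
M03>=2 -> cell3
M04>=2 -> cell4
M07>=1 -> cell5
```

Each line is one rule: integer conditions on motif counts joined by `&`,
then the cell type it predicts.  The planted grammar is recovered — each
non-default class gets a rule naming its planted motif with a threshold
within ±1 of the planted minimum (a forest separating counts {0} from
{3, 4} legitimately splits at ≥ 2).  `cell1` reports no rule because the
rule-list classifier's default prediction already covers the
alphabetically first class — the same reason real runs leave some cell
lines with "No rule identified".  Alongside `grammar.txt` the run writes
the count matrix (`counts.tsv`), the serialized forest (`model.json`),
the importance table (`importance.tsv`, sorted by scaled MDA), rule
metrics (`rules.tsv`/`rules.json`), cross-validation metrics
(`cv.tsv`/`cv_summary.json`; here mean AUROC 1.0 for every class — the
planted signal is strong and clean) and the resolved configuration.

Other subcommands: `scan`, `train`, `importance`, `rules`, `evaluate`
(each stage resumable from the previous stage's files) and `sweep`
(cross-validate a grid of window half-widths and recommend the best; on
the benchmark the 240 bp operating point wins).

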