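# promoterbench

A benchmarking framework for *E. coli* σ<sup>70</sup> promoter-region
predictors, for computational biologists who build or evaluate bacterial
regulatory-element classifiers.

Promoter identification is a binary classification task with a structural
weakness: there is no experimentally validated *non*-promoter data, so every
study manufactures its own negatives. The choice of recipe — random
sequences, coding-region windows, or intergenic windows split by the
orientation of the flanking genes — changes the apparent performance of a
predictor dramatically, and cross-validation estimates obtained under one
recipe can collapse on an independent test set built under another.
`promoterbench` implements the full assessment pipeline needed to measure
and compare predictors under controlled negative-data conditions:

- **Data sets** — fixed-length 81-nt windows spanning [TSS−60, TSS+20];
  six negative-generation strategies (random background with T/G/C/A =
  0.28/0.22/0.22/0.28, coding, convergent / divergent / codirectional±
  intergenic) plus an equal-shares *mixed* combiner; greedy redundancy
  reduction at a pairwise global-alignment identity cutoff (default 45%).
- **Synthetic data** — seeded generators for promoter windows with planted,
  jittered, degenerate −35 (`TTGACA`, offset 22) and −10 (`TATAAT`, offset
  49) boxes, and for annotated genomes realizing all four intergenic
  categories, so the entire pipeline runs fully offline.
- **Encodings** — k-mer composition (4^k features, normalized overlapping
  counts), positional nucleotide / dinucleotide identity (NID: 81 nominal
  features; DNID: 80), one-hot ("orthogonal") codification, and smoothed
  structural profiles under twelve bundled dinucleotide physicochemical
  scales M1–M12 (A-philicity, twist variants, bending stiffness, melting,
  Z-DNA and duplex free energies, deformability, propeller twist, stacking
  energy).
- **Classifiers** — Naive Bayes with the posterior-ratio decision rule
  (Laplace-smoothed nominal terms, Gaussian numeric terms), random forest
  (100 trees, per-split subspace of ⌈√M⌉ features), linear/RBF SVM, a
  fixed-length profile HMM scored by log-odds against an i.i.d. background,
  and a meta-predictor averaging two base models' probabilities.
- **Evaluation** — ACC, Sn, Sp, MCC at a threshold; ROC and the
  Mann–Whitney (midrank) AUC; AUC grading bands; repeated stratified
  k-fold cross-validation; train/test grids over negative strategies.
- **Statistics** — Demšar's procedure: tie-averaged ranks per data set,
  Friedman χ²<sub>F</sub> = [12N/(k(k+1))]·[Σ<sub>j</sub> R̄<sub>j</sub>² −
  k(k+1)²/4], and the Nemenyi post-hoc with critical difference
  CD = q<sub>α</sub>·√(k(k+1)/(6N)).
- **Feature analysis** — per-group structural profiles and information-gain
  ranking (H(C) − H(C|X), Fayyad–Irani MDL discretization, fold-averaged).

## Worked example

Cross-validate a Naive Bayes classifier on dinucleotide-identity features
over synthetic promoters versus composition-matched random negatives:

```python
import promoterbench as pb

pos = pb.make_synthetic_promoters(500, seed=11)   # planted -35/-10 boxes
neg = pb.generate_random_negatives(500, seed=12)  # E. coli-like background
trainer = pb.make_trainer("nb", "DNID")
rec = pb.repeated_cv(trainer, pos, neg, k=10, runs=10, seed=0)
print(f"{rec.model_id}: mean AUC {rec.metrics['AUC']:.3f} "
      f"({pb.grade_auc(rec.metrics['AUC'])}) over {rec.cv_config['runs']} runs")
```

prints

```
NB_DNID: mean AUC 0.976 (Excellent) over 10 runs
```

meaning: pooling the held-out scores of each 10-fold split, a random
planted-motif window outranks a random background window 97.6% of the time,
averaged over ten shuffled repetitions — an "Excellent" AUC band (≥ 0.90).
The same machinery drives the command line:

```bash
promoterbench generate --n-positives 500 --n-negatives 500 \
    --strategies random,coding,convergent,mixed --out data/
promoterbench crossval --pos data/positives.fasta --neg data/neg_mixed.fasta \
    --algorithm nb --encoding DNID --k 10 --runs 10 --out cv.json
promoterbench run --config src/promoterbench/configs/negative_shift_grid.yaml
promoterbench ranktest out/negative_shift_grid/results.tsv
```

## Using the published benchmark data

The curated cross-validation and independent-test sets (579 / 792 promoter
windows with seven matched negative versions each) are distributed as the
defining study's supplementary archive and are not redistributed here.
Place the extracted FASTA files under `data/s1_dataset/` following the
layout documented in `promoterbench.s1`; `load_s1_dataset` then returns the
sets ready for the same train/grid/rank machinery, and the benchmark
reproduction tests in `tests/test_acceptance.py` become runnable.

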