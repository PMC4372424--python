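# Methods

## The assessment problem

A σ70 promoter-region predictor is a binary classifier over fixed-length
DNA windows. The window convention is 81 nt spanning [TSS−60, TSS+20] with
the transcription start site at biological position 0 (window coordinate
60); the canonical −10 element therefore sits near window offsets 49–54
and the −35 element near 22–27. Because validated non-promoter data do not
exist, the framework treats the *negative-generation strategy* as an
explicit experimental factor: every evaluation names which of the six
strategies (random background, coding, convergent / divergent /
codirectional+ / codirectional− intergenic) or the mixed combination
produced its negatives, and the core experimental designs — repeated
cross-validation per strategy, and the full train-strategy × test-strategy
grid — quantify how much a predictor's measured AUC depends on that choice.

## Data-set construction

**Redundancy reduction.** Pairwise similarity is global-alignment identity:
match +1, mismatch 0, linear gap penalty 1, identity = matches / alignment
length (Biopython's pairwise aligner). Reduction is greedy keep-first: a
window survives if its identity with every earlier survivor (and, for test
sets, with every reference window) is at most the cutoff, default 0.45.
The greedy order makes the procedure deterministic. Note that two random
81-nt windows already align near ~55% identity under this scoring, so a
45% cutoff is aggressive by construction and survivor counts depend
strongly on the identity definition — an inherent caveat when comparing
counts across tools.

**Negative strategies.** Random negatives cut 81-nt windows at uniform
start positions (with replacement) from a single 10^6-nt sequence drawn
i.i.d. with base probabilities T/G/C/A = 0.28/0.22/0.22/0.28. Coding and
intergenic negatives sample windows wholly contained in the target
regions, choosing a region with probability proportional to its number of
valid start offsets so placement is uniform over all valid positions.
Intergenic regions are the gaps between adjacent annotated genes,
categorized by the flanking strand pair: (+,−) convergent, (−,+)
divergent, (+,+) codirectional+, (−,−) codirectional−; zero-length gaps
are skipped, and windows are taken on the forward strand as written (no
reverse-complementing — the extraction strand is a documented convention,
not a biological claim). The mixed set draws without replacement from the
six strategy sets in shares that differ by at most one, larger shares to
earlier sets in the canonical order (579 total → 97,97,97,96,96,96);
per-record provenance is preserved.

## Synthetic data: what it emulates and what it does not

The generator plants degenerate σ70 box signals in background windows:
`TTGACA` at offset 22 and `TATAAT` at offset 49, each shifted by a uniform
jitter of ±2 nt and then per-position mutated to a uniform random base
with probability 0.15. The defaults give a strong but imperfect signal
whose discriminative footprint falls in window positions ≈45–55, the
region where real promoter windows carry their strongest structural
signature. Synthetic genomes pack non-overlapping genes (≥300 nt, gaps
≥120 nt) with i.i.d. strands and are re-drawn until all four intergenic
categories exist, so every strategy is exercisable offline.

Deliberate simplifications: (i) both boxes are planted at the *same*
fidelity, whereas real −35 elements are substantially more degenerate than
−10 elements — consequently the −35 box contributes a stronger secondary
feature-importance signal here than on real data, and analyses that on
real promoters are dominated by the −10 region (e.g. the top-10
information-gain positions) split between the two planted neighborhoods on
synthetic data; (ii) synthetic coding and intergenic windows share the
random background's base composition, so compositional contrasts between
strategies are much weaker than in a real genome — strategy-shift effects
are therefore directional, not magnitude-calibrated; (iii) no spacer-length
constraint couples the two boxes and no extended −10 or UP element is
modeled. Passing tests on synthetic data demonstrate that the pipeline
detects and localizes a planted signal under realistic noise; they do not
certify real-data AUC levels.

## Feature encodings

k-mer: 4^k features in lexicographic order, value = overlapping count /
(L−k+1), so rows sum to 1. NID/DNID: one nominal feature per position /
adjacent pair (categories ACGT / the 16 dinucleotides). One-hot expansion
("orthogonal codification") turns each nominal column with c categories
into c indicators (81→324, 80→1280) for classifiers that need numeric
input. Structural profiles map each dinucleotide step to its value under
one of twelve bundled scales and smooth with a centered moving average,
default width 3, edge windows truncated (shrinking), preserving d = L−1;
width 1 reproduces the raw profile. Profiles are not z-scored before
smoothing, and scales are applied to the written strand only — all bundled
scales are reverse-complement symmetric, so strand averaging would be a
no-op anyway (verified by test). Scale tables live in
`data/scales/M*.tsv` with per-scale citation and a confidence marker;
values were transcribed from the cited primary literature via the standard
compilations of the promoter-structure field, and sign/unit conventions
can differ across editions (flagged per file).

## Classifiers

**Naive Bayes** implements the posterior-ratio decision rule under
attribute independence. Nominal attributes use Laplace-smoothed category
frequencies (α = 1 by default; α is the pseudo-count added to every
category); numeric attributes use Gaussian class-conditional densities
with a relative variance floor of 10⁻⁹·max-feature-variance to keep
near-constant features finite. Scoring returns the normalized posterior
P(C=1|X).

**Random forest** (scikit-learn): 100 fully grown trees on bootstrap
samples, per-split subspace m = ⌈√M⌉ (the paper-style "m ≪ M" choice made
concrete); the score is the forest-averaged tree probability.
**SVM** (scikit-learn SVC): linear or RBF kernel, cost 1, γ = 1/d by
default, deliberately untuned; the ranking score is the signed decision
value through a logistic squash — monotone, so AUC is unaffected by the
mapping.

**Profile HMM.** The architecture is a length-L profile with match,
insert and delete states, but training windows are fixed-length and
ungapped, so re-estimation concentrates virtually all mass on the
all-match path: match emissions converge to position-specific smoothed
base frequencies (pseudo-count 1), which the bounded re-estimation loop
verifies by log-likelihood convergence (tolerance 10⁻⁹). Insert/delete
transitions are retained structurally at probability 0.01 and contribute a
per-model constant. A query scores the log-odds of the match path against
an i.i.d. background of the training set's pooled base frequencies,
squashed to [0,1] logistically. This is a faithful-but-degenerate profile
HMM: with gapped or variable-length data the simplification would not
hold, and no exact correspondence to any specific HMM implementation is
promised.

**Meta-predictor**: the per-instance mean of two base models'
probabilities, each model encoding the query set under its own tag; the
combined score is bounded by the component scores.

## Evaluation and comparison

Confusion counts use score ≥ threshold → positive. ACC, Sn, Sp, MCC follow
the standard definitions; a vanished denominator reports the metric as
missing (MCC as 0 with a degenerate flag) instead of raising. AUC is
computed by midranks (Mann–Whitney), ties worth ½ — identical to
exhaustive positive×negative pair counting, which the tests verify — and
is invariant under monotone score transforms. Grading bands: ≥0.90
Excellent, 0.80–0.89 Good, 0.70–0.79 Fair, 0.50–0.69 Poor, with a sub-0.50
"Fail" extension below the published bands.

Repeated CV uses stratified folds (the 1:1 class design makes
stratification the stable choice), default 10 runs × 10 folds; per run the
held-out scores are pooled into one AUC (less noisy than per-fold
averaging at n ≈ 10³; per-fold averaging is available by flag), and the
report is the mean over runs with per-run values retained. Unstratified
splitting with k = n gives leave-one-out. Grid experiments produce a tidy
(model, train, test, AUC) table; the pivoted per-model table carries
Average and population-STD margin rows.

Classifier comparison follows Demšar: tie-averaged ranks per data set
(rank 1 best), the plain chi-square Friedman statistic with df = k−1 (the
Iman–Davenport F correction is available behind a flag), and the Nemenyi
post-hoc with CD = q_α·√(k(k+1)/(6N)), q_α bundled for k = 2–20 at α ∈
{0.05, 0.10} and cross-checked against the studentized-range distribution.
Groups are maximal average-rank-consecutive sets with no internal
significant pair, as drawn in a critical-difference diagram.

## Feature analysis

Group profiles are per-group column means of a numeric feature matrix;
the promoter-versus-negative profile deviation localizes the
discriminative region. Information gain is H(C) − H(C|X) in bits, with
numeric features discretized by Fayyad–Irani MDL binning refit inside each
training fold (equal-width binning available as a fallback); the ranking
reports the fold-mean gain, sorted descending with ties broken by feature
index. Fold aggregation by mean is a documented convention.

## Problem sizes and determinism

Default study sizes: 1000 windows per class for signal-recovery
experiments, 400 per class and strategy for shift grids and the
six-classifier comparison, 500 per class for held-out test sets — sizes at
which the planted signal's detection is stable while a full pipeline run
completes in seconds. Every stochastic stage takes an explicit seed; the
experiment runner derives stage seeds from one master seed and records
them in a manifest, making any run bit-reproducible.

## Known limitations

- Survivor counts under the 45% cutoff are definition-dependent (see
  above); reproducing published set sizes exactly from raw database dumps
  is not expected.
- Bundled scale values may differ from specific primary-source editions in
  sign or units; per-file confidence markers identify transcriptions made
  via secondary compilations.
- The profile HMM's insert/delete machinery is structurally present but
  untrained in the degenerate fixed-length regime.
- Synthetic strategy contrasts are compositionally flat (see above), so
  cross-strategy degradation magnitudes on synthetic data understate
  real-data effects.
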