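# Minimal end-to-end smoke run: synthetic promoters vs random negatives,
# Naive Bayes on dinucleotide identity, 2 runs of 5-fold CV.
name: synthetic_smoke
seed: 7
window_length: 81
data:
  synthetic:
    n_positives: 200
    n_negatives: 200
  strategies: [random]
models:
  - {algorithm: nb, encoding: DNID}
evaluation:
  mode: cv
  k: 5
  runs: 2
output: out
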