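# Train/test grid over negative strategies: trains each model on every
# negative strategy and tests on every strategy of a fresh synthetic
# draw, exposing how sensitive an encoding is to the negative-data recipe.
name: negative_shift_grid
seed: 11
window_length: 81
data:
  synthetic:
    n_positives: 300
    n_negatives: 300
  strategies: [random, coding, convergent, divergent, copos, coneg, mixed]
models:
  - {algorithm: nb, encoding: DNID, id: NB_DNID}
  - {algorithm: nb, encoding: "kmer:4", id: NB_4-mer}
evaluation:
  mode: grid
output: out
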