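# Structure-based representations: cross-validate classifiers on the
# bending-stiffness (M4) and twist (M3) profiles to compare a strongly and
# a weakly discriminative physicochemical scale.
name: structure_scales
seed: 13
window_length: 81
data:
  synthetic:
    n_positives: 300
    n_negatives: 300
  strategies: [random, mixed]
models:
  - {algorithm: nb, encoding: "struct:M4"}
  - {algorithm: nb, encoding: "struct:M3"}
  - {algorithm: rf, encoding: "struct:M4"}
  - {algorithm: rf, encoding: "struct:M3"}
evaluation:
  mode: cv
  k: 5
  runs: 2
output: out
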