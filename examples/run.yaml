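landmarks: scratch/sim/landmarks.csv
metadata: scratch/sim/metadata.csv
scheme: table3
regions: [whole_skull, neurocranium, viscerocranium, viscerocranium_non_oral, oral]
seed: 1
alpha: 0.01
size_correction: true
plan: {n_bootstrap: 1000, n_permutations: 1000}
groupings:
  - label: all
    filter_a: {clade: marsupial}
    filter_b: {clade: placental}
    label_a: marsupial
    label_b: placental
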