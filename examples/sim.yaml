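scheme: table3
seed: 1
sex_ratio: 0.5
size_distribution: [2.0, 0.3]
groups:
  - {label: mars, clade: marsupial, n_specimens: 30, planted_variance: 0.018}
  - {label: plac, clade: placental, n_specimens: 40, planted_variance: 0.052}
ecology_assignment:
  mars: {diet: omnivore, habitat: terrestrial, activity: nocturnal_crepuscular}
  plac: {diet: omnivore, habitat: terrestrial, activity: nocturnal_crepuscular}
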