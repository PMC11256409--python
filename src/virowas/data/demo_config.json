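{
  "seed": 0,
  "n_permutations": 199,
  "sim": {
    "n_case": 12,
    "n_control": 12,
    "n_votus": 30,
    "n_planted_case_enriched": 6,
    "n_planted_control_enriched": 6,
    "effect_fold": 4.0,
    "genome_length_range": [2100, 3200],
    "mean_depth": 8.0,
    "dropout_rate": 0.05,
    "n_decoys": 10,
    "n_duplicates": 3,
    "n_external": 4,
    "seed": 0
  }
}
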