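# Default demo run configuration.
seed: 0
out_dir: run
generator:
  n_patients: 500
  notes_per_patient: [1, 3]
  sentences_per_note: [4, 10]
nlp: {}
predict:
  grid: [[0.3, 0.05]]
  k_outer: 10
  comparators: false
stages: [simulate, phenotype, cohort, outcomes, predict]
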