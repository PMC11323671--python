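# Full evaluation run on simulated cohorts.
#
# "real" can also point at on-disk CSVs:
#   real: {static: data/static.csv, sequences: data/sequences.csv}
# and "synthetic" can be derived from the real cohort for calibration:
#   synthetic: {derive: holdout, fraction: 0.5}
#   synthetic: {derive: mode_collapse, k: 3}

out_dir: runs/demo
seed: 1
k_folds: 10

real:
  generate:
    n_patients: 500

synthetic:
  generate:
    n_patients: 500
    shift: 0.3          # transition matrices mixed toward a permuted reference

evaluations: [descriptives, projections, gof, utility, privacy]

projection:
  methods: [tsne, umap]
  neighbor_values: [15, 25, 50]
  mixing_k: 10

train:
  max_epochs: 20
  patience: 4
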