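# Bundled synthetic demo: small cohort with three planted binary-mechanism
# taxa (two risk-increasing, one risk-decreasing). Runs in about a minute.
outdir: smcvd_demo_run
simulate:
  n_subjects: 240
  n_taxa: 40
  n_planted_binary: 3
  n_planted_continuous: 0
  effect_sizes: [0.8, 0.8, -0.8]
  noise_sd: 0.3
  library_size_range: [2000, 10000]
  strata_fractions: [0.84, 0.11, 0.05]
  seed: 20210
rank: genus
n_splits: 25
train_fraction: 0.8
cv_folds: 10
threshold: 0.8
anosim_permutations: 199
master_seed: 7
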