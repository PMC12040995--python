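# The packaged 21-species synthetic collection: 21 host species in one
# region, fleas and mites (42 networks), moderate sex effects drawn per
# species.  Null/permutation sizes reduced from the full-scale defaults
# (1000 / 10000) to keep a complete run in the minutes range.
simulate:
  n_species: 21
  hosts_per_sex: 25
  n_parasites: 12
  nb_mean: 8.0
  nb_dispersion: 1.0
  abundance_mult_range: [1.0, 2.5]
  composition_shift_range: [0.0, 0.1]
  parasite_prevalence_decay: 0.75
  regions: [north]
  seed: 7
min_per_sex: 20
n_null: 200
nperm: 999
standardize_db_manova: true
response_scale: zscore
percentile: 95.0
seed: 7
outdir: collection21_out
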