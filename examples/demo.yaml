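# Small demonstration run: 4 simulated host species, one region, both
# parasite groups, reduced null/permutation sizes so it finishes in seconds.
simulate:
  n_species: 4
  hosts_per_sex: 25
  n_parasites: 12
  nb_mean: 8.0
  nb_dispersion: 1.0
  male_abundance_mult: 1.5
  male_composition_shift: 0.05
  parasite_prevalence_decay: 0.75
  regions: [north]
  seed: 42
min_per_sex: 20
n_null: 100
nperm: 999
standardize_db_manova: true
response_scale: zscore
percentile: 95.0
seed: 42
outdir: demo_out
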