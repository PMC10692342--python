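# small synthetic run: finishes in a few minutes on one CPU
seed: 1
covariate: s_pc1
regime: reference
scale:
  n_herds: 4
  n_stations: 3
  n_years: 5
  n_dams: 150
  n_sires: 16
  n_genotyped_sires: 12
  n_snps: 200
fit:
  max_iter: 80
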