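# High-expression cell-line preset: parameters chosen so the expected
# eluate conjugate-DNA concentration lands near 79 nM, the top of the
# observed per-cell-line range (documentation preset, not an assertion).
name: cellline_high
population:
  n_ev: 1000000
  tumor_fraction: 0.3
  antigen_mean: 28000000
  antigen_dispersion: 5
labeling:
  p_bind: 0.3
  nonspecific_rate: 0.05
  dna_per_conjugate: 3
capture:
  capture_eff: 0.7
  wash_retention: 0.9
  eluate_volume: 100.0
qpcr:
  slope: 4.059
  intercept: 8.144
  noise_sd: 0.2
  max_cycles: 40
  ref_conc_nM: 100.0
  standard_xs: [0, 1, 2, 3, 4]
  standard_replicates: 3
quantify:
  dna_per_ab: 3
  mw_kda: 29.1
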