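# Baseline synthetic assay: a heterogeneous EV prep with a 30% tumor
# fraction, over-dispersed antigen copy numbers, realistic labeling and
# bead-capture losses, and replicate qPCR noise of 0.2 cycles against the
# published C1C2 standard curve.
name: default
population:
  n_ev: 10000
  tumor_fraction: 0.3
  antigen_mean: 50
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
  ref_conc_nM: 10.0
  standard_xs: [0, 1, 2, 3, 4]
  standard_replicates: 3
pla:
  p_ligate: 0.9
  background_rate: 0.5
quantify:
  dna_per_ab: 3
  mw_kda: 29.1
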