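# Blood-bank units stored in SAGM to expiry: six samples, stored-group
# subunit means/SDs (gamma already elevated), AER 1.54 +/- 0.12.
name: stored-unit
cohort:
  n_fresh: 0
  n_stored: 6
  mu:       {HBB: 34.5, HBA1: 33.9, HBD: 29.1, HBM: 25.2, HBG2: 26.7, HBQ1: 23.4}
  sigma:    {HBB: 0.6, HBA1: 0.2, HBD: 1.1, HBM: 1.4, HBG2: 0.8, HBQ1: 1.5}
  subunit_corr:
    - [1.00, 0.82, 0.76, 0.25, 0.37, 0.42]
    - [0.82, 1.00, 0.76, 0.07, 0.08, 0.46]
    - [0.76, 0.76, 1.00, 0.63, 0.43, 0.39]
    - [0.25, 0.07, 0.63, 1.00, 0.21, 0.54]
    - [0.37, 0.08, 0.43, 0.21, 1.00, 0.26]
    - [0.42, 0.46, 0.39, 0.54, 0.26, 1.00]
  aer_corr: {HBB: -0.606, HBA1: -0.722, HBD: -0.687, HBM: 0.0, HBG2: 0.0, HBQ1: 0.0}
  aer_mean: 1.54
  aer_sd: 0.12
  stored_gamma_shift: 0.0
  psd_repair: true
er:
  aer_target: 1.54
  spread: 0.25
  nd_fraction: 0.03
field:
  width_px: 1280
  height_px: 960
  n_cells: 400
  mean_cell_area_px: 250
  orientation_jitter_deg: 8.0
  noise_sd: 0.01
  background_gradient: 0.05
  allow_touching: false
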