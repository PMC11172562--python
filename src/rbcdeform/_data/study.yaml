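# Default cohort design: the full 15-sample study (9 fresh donors + 6
# stored blood-bank units).  Subunit means/SDs are the pooled cohort
# values; the gamma (HBG2) mean is the fresh-group value and the storage
# effect is carried by stored_gamma_shift.  The gamma SD is the
# within-group spread (the pooled SD is inflated by the storage shift).
name: study
cohort:
  n_fresh: 9
  n_stored: 6
  mu:       {HBB: 34.4, HBA1: 34.0, HBD: 29.1, HBM: 25.7, HBG2: 24.4, HBQ1: 23.3}
  sigma:    {HBB: 0.5, HBA1: 0.4, HBD: 0.9, HBM: 1.1, HBG2: 0.65, HBQ1: 1.1}
  subunit_corr:  # order HBB, HBA1, HBD, HBM, HBG2, HBQ1
    - [1.00, 0.82, 0.76, 0.25, 0.37, 0.42]
    - [0.82, 1.00, 0.76, 0.07, 0.08, 0.46]
    - [0.76, 0.76, 1.00, 0.63, 0.43, 0.39]
    - [0.25, 0.07, 0.63, 1.00, 0.21, 0.54]
    - [0.37, 0.08, 0.43, 0.21, 1.00, 0.26]
    - [0.42, 0.46, 0.39, 0.54, 0.26, 1.00]
  aer_corr: {HBB: -0.606, HBA1: -0.722, HBD: -0.687, HBM: 0.0, HBG2: 0.0, HBQ1: 0.0}
  aer_mean: 1.56
  aer_sd: 0.10
  stored_gamma_shift: 2.3
  psd_repair: true
er:
  aer_target: 1.56
  spread: 0.25
  nd_fraction: 0.02
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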