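# Default experiment configuration: the calibrated two-arm xenograft cohort
# (15 hepatocellular carcinoma + 9 cholangiocarcinoma mice) with full wave
# simulation, pressure readings and histology rendering.  Any field of the
# cohort/acquisition/histology/analysis sections may be overridden; omitted
# fields keep the packaged calibration (group means and SDs, structural
# betas, R^2 values and the covariate correlation matrix).
seed: 0
cohort:
  n_hcc: 15
  n_cca: 9
  compression_levels_kpa: [0.0, 2.0, 4.0]
  phase_noise_sd_rad: 0.01
  pressure_noise_sd_mmhg: 0.3
acquisition:
  simulate_waves: true
  matrix_rows: 87
  matrix_cols: 67
  n_slices: 9
  voxel_size_um: [300.0, 300.0, 350.0]
  vibration_frequency_hz: 600.0
  n_offsets: 4
  encoding_efficiency_rad_per_um: 2.0
  roi_fraction: 0.75
histology:
  simulate: true
  picrosirius_tile: [384, 384]
  picrosirius_pixel_um: 2.0
  nucleus_field_area_mm2: 1.0
  nucleus_overlap_fraction: 0.1
  nucleus_pixel_um: 1.0
analysis:
  solid_stress_cutoff_mmhg: 15.6
  collagen_cutoff_percent: 1.7
  stepwise_p_enter: 0.05
  stepwise_p_remove: 0.10
  n_repeatability_subjects: 5
outputs:
  save_nifti: true
  save_tiles: true
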