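# spbkit imaging simulate --config examples/imaging_sim.yaml --seed 1 --out im_data
params:
  n_cells: 8
  field_size_px: [1000, 1000]
  pixel_size_um: 0.065
  cell_length_um_range: [7.0, 12.0]
  cell_width_um: 3.5
  frac_cells_with_cyclin_spot: 0.5
  spot_diameter_um: 0.35
  spot_intensity: 150.0
  spb_marker_intensity: 150.0
  cell_background_intensity: 100.0
  camera_noise_sd: 5.0
  n_frames: 1                     # > 1 for a time-lapse
  spb_detectable_frac_frames: 1.0 # < 1 exercises the two-of-three rule
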