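# spbkit imaging run --config examples/imaging_run.yaml --mode still --out results
# Quality and segmentation thresholds are empirical per experiment; the
# values below are calibrated on the simulator defaults (see docs/methods.md).
mode: still
paths:
  cyclin: im_data/cyclin.tif
  spb: im_data/spb.tif
  edge: im_data/edge.tif
params:
  pixel_size_um: 0.065
  diameter_um: 0.35
  quality_threshold_cyclin: 8.0
  quality_threshold_spb: 8.0
  autofluorescence_background: 0.0
  segmentation:
    adaptive_window_px: 121
    adaptive_offset: 30.0
    background_intensity_threshold: 100.0
    erosion_radius_px: 4
    dilation_radius_px: 4
    min_area_px: 500
    min_mean_intensity: 100.0
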