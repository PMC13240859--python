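optics:
  tilt_deg: 33.8
  step_um: 10.73
  pixel_um: 0.8
  frame_shape: [168, 96]
  slab_thickness_um: 6.0
  psf_sigma_px: 0.5
  bit_depth_max: 65535
lanes:
  - lane_id: cell01
    path: example_out/scan/cell01.tif
    crop:
      height_px: 150
      width_px: 80
      start_height_px: 8.0
      end_height_px: 12.0
      width_offset_px: 8
      allowed_widths: [80]
    condition_label: ''
detection:
  log_threshold: 150.0
binning:
  n_bins: 51
  search_window_um: [180.0, 320.0]
out_dir: example_out/out
seed: 7
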