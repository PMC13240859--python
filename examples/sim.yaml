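# One desk-scale lane: antibody-analogue band at 250 um plus three
# sample bands, five impurities, ~700 um of migration in 80 frames.
optics:
  frame_shape: [168, 96]
lane:
  n_frames: 80
  lane_width_um: 56.0
  depth_min_um: 5.0
  depth_max_um: 45.0
  width_offset_px: 12
  interface_start_px: 8.0
  interface_end_px: 12.0
bands:
  - {center_um: 250.0, width_um: 28.0, expected_count: 1600}
  - {center_um: 330.0, width_um: 45.0, expected_count: 140}
  - {center_um: 470.0, width_um: 50.0, expected_count: 160}
  - {center_um: 610.0, width_um: 55.0, expected_count: 150}
impurities:
  count: 5
lane_length_um: 700.0
lane_id: cell01
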