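# Default synthetic-microscopy scene: six textured macrophage-like cells
# in a 102 x 102 um field, two NP channels accumulating spots linearly.
scene:
  shape: [512, 512]
  n_z: 3
  pixel_size: 0.2
  n_cells: 6
  cell_radius_um: [6.0, 9.0]
  bf_background: 1000.0
  texture_amplitude: 200.0
  fluor_background: 20.0
  gaussian_noise_sd: 3.0
  poisson_gain: 1.0
uptake:
  rates: {NP1: 8.0, NP2: 8.0}
  coloc_fraction: 0.5
  marker_overlap: 0.5
t_hours: 2.0
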