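# Bundled end-to-end demo: two morphologically distinct synthetic
# conditions, three replicate wells each.  Sized to finish in well under a
# minute while exercising every pipeline stage.
seed: 42
calibration_um_per_px: 2.0
conditions:
  - name: control
    replicates: 3
    synth:
      n_cells: 130
      length_mean: 110.0
      length_sd: 18.0
      width_mean: 26.0
      width_sd: 4.0
      overlap_fraction: 0.1
      min_gap_px: 6.0
      halo_width_px: 1.0
      image_shape: [1000, 1000]
      noise_sd: 900.0
      background_gradient_amplitude: 2000.0
  - name: disease
    replicates: 3
    synth:
      n_cells: 130
      length_mean: 70.0
      length_sd: 30.0
      width_mean: 20.0
      width_sd: 6.0
      overlap_fraction: 0.1
      min_gap_px: 6.0
      halo_width_px: 1.0
      image_shape: [1000, 1000]
      noise_sd: 900.0
      background_gradient_amplitude: 2000.0
segmentation:
  background_kernel_px: 151
  texture_window_px: 5
  min_object_area_px: 120
  closing_radius_px: 2
profiling:
  n: 200
  n_bootstrap: 10
  min_cells_per_well: 60
  max_cells_per_well: 5000
classifier:
  n_train_bootstrap: 10
  train_sample_size: 300
  n_trees: 100
  n_cv_groups: 5
analysis:
  standardize: true
  umap: false
  figure: false
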