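# Demo pipeline: textured 25-mm slab with a surgical clip and a
# microcalcification, noisy fast-mode acquisition, perspective
# reconstruction with artifact reduction, flavoring, and a synthetic
# mammogram with an ROI CNR readout.  Sized to run in well under a
# minute on one CPU.
out_dir: tomobreast_demo
geometry:
  detector_shape: [64, 144]
  focal_spot: {ffs_enabled: true}
stages:
  - phantom:
      seed: 11
      thickness_mm: 25.0
      glandularity: 0.3
      texture_beta: 3.0
      shape: [144, 32, 10]
      voxel_size_mm: [0.25, 0.25, 2.5]
      inserts:
        - kind: clip
          position_mm: [-2.0, 0.0, 12.0]
          size_mm: [3.0, 1.0, 1.0]
          material: Rh
          density_scale: 0.35
        - kind: microcalc_cluster
          position_mm: [1.5, 0.5, 12.0]
          count: 1
          spacing_mm: 0.0
          size_mm: [0.4]
          density_scale: 8.0
  - simulate:
      seed: 5
      n_spot_samples: 1
      n_time_samples: 1
      step_mm: 1.25
      noise_gain: 100000.0
  - recon:
      zmin: 2.0
      zmax: 22.0
      spacing: 2.0
      window: hann
  - artifact_reduction: {}
  - postproc:
      n_bands: 3
      band_gains: [1.2, 1.1, 1.0]
      overshoot_clamp: 0.5
  - sm:
      gain: 100000.0
      clamp_k: 2.0
      detail_weight: 0.5
  - metrics:
      cnr:
        on: sm
        obj_rows: [34, 42]
        obj_cols: [85, 93]
        bg_rows: [8, 24]
        bg_cols: [16, 48]
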