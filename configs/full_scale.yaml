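# Full-scale profile: 6000 px images (14,400 patches/patient), 64^3 volumes,
# 153 patients, k=20. Hours of compute; the test-scale profile is the default.
synthetic:
  n_patients: 153
  image_size: 6000
  patch_size: 50
  n_texture_classes: 6
  volume_shape: [64, 64, 64]
  lesion_axes_range: [[5.0, 18.0], [4.0, 14.0], [3.0, 10.0]]
  seed: 0
k_clusters: 20
screen_alpha: 0.2
block_targets: {CT: 8, pathology: 5, clinical: 4}
seed: 0
run_loocv: true
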