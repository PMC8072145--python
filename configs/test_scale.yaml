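# Fast profile: 600 px images, 32^3 volumes, 20 patients, k=8.
synthetic:
  n_patients: 20
  image_size: 600
  patch_size: 50
  n_texture_classes: 6
  volume_shape: [32, 32, 32]
  lesion_axes_range: [[4.0, 10.0], [3.0, 8.0], [3.0, 7.0]]
  seed: 0
k_clusters: 8
screen_alpha: 0.2
block_targets: {CT: 8, pathology: 5, clinical: 4}
seed: 0
run_loocv: true
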