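# Desk-demo configuration: a miniature synthetic study that exercises every
# pipeline stage (simulate -> preprocess -> cross-validated train -> evaluate
# -> explain) in a few minutes on one CPU. For the full reference study just
# drop the `simulate` and `evaluate` overrides (defaults are 15/10/5 + 2/3/3
# volumes, 14 frames each, fivefold cross-validation).
master_seed: 1
simulate:
  train_volumes: {NOR: 2, GBM: 2, PCNSL: 2}
  test_volumes: {NOR: 1, GBM: 1, PCNSL: 1}
  frames_per_volume: 12
  acq:
    n_depth_pixels: 128
    n_lateral_pixels: 256
train:
  max_epochs: 5
evaluate:
  n_folds: 2
  n_cam_examples: 4
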