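# Quick end-to-end profile: simulates 8 bead fields at 32 px, builds the
# paired dataset, trains a small translator for 2 epochs, and evaluates
# the defocus sweep.  Scale grid/n_fields/epochs up for real runs.
seed: 0
out_dir: tieqpi_run
optical:
  magnification: 20.0        # 0.1725 um object pitch
phantom:
  kind: bead                 # bead | cell
  n_fields: 8
  grid: 32
z:
  min: -60.0
  max: 60.0
  step: 15.0
tie:
  derivative: central
  eps: 0.0
  floor: 1.0e-3
  boundary: mirror
dataset:
  split: [30, 12, 12]
gan:
  base_channels: 4
  epochs: 2
  batch_size: 4
  learning_rate: 1.0e-4
  l1_weight: 100.0
  dropout: 0.5
metrics:
  L: 255.0
  K1: 0.01
  K2: 0.03
  window: 8
evaluate:
  n_stacks: 2
infer:
  n_images: 4
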