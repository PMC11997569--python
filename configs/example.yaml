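# Example pipeline configuration for a synthetic end-to-end run.
# All sections are optional; unknown keys are rejected.
seed: 0
run_dir: runs/example

io:
  simulate: true          # or set `input: path/to.csv` with `format: wide|long`
  n_per_class: 2
  session_lengths_s: [330.0, 330.0]
  minmax: true

preprocess:
  delta: 900.0            # session gap threshold (s)
  window_s: 60.0
  overlap: 0.5
  completeness: 0.95

augment:
  enabled: true
  sigma: 0.02             # jitter sd in scaled-signal units
  copies: 1

features:
  subframes: 12
  stats: [mean, std, min, max]
  freq_bins: 64
  include_hrv: false

balance:
  enabled: true
  k: 5

model:
  variant: full           # full | no_freq | no_time
  conv_filters: [32, 64, 128]
  kernel: 3
  pool: 2
  dropout: 0.3
  hidden: [128, 64]

train:
  lr: 0.001
  l2: 0.0001
  epochs: 50
  batch: 64
  patience: 10

tune:
  mode: grid
  epochs: 5               # reduced per-cell budget for the 27-cell sweep

eval:
  fraction: 0.8
  by: window
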