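# Example configuration driving all three CLI commands.
seed: 42
out: results

min_cells: 1        # timepoints with fewer observed cells are dropped
f_threshold: 5.0    # nested-model F decision threshold
n_reps: 1000        # Monte-Carlo replicates for `validate`

# Wound edge: a straight line through p1 and p2; interior_sign selects
# the tissue side (+1 puts tissue at positive x for a vertical line).
wound:
  p1: [0.0, 0.0]
  p2: [0.0, 1.0]
  interior_sign: 1

# Spatial histogram: 100-um bins centred 50, 150, ..., 950 um.
bins:
  width: 100.0
  first_center: 50.0
  last_center: 950.0

# Scenario for `simulate`: a cohort released in the 80-um wound zone,
# observed every 10 min for 16 h.
simulate:
  n_subjects: 6
  v: 0.26           # drift, um/min (negative = toward the wound)
  D: 8.0            # diffusion, um^2/min
  n_cells: 200
  t_end: 960
  dt: 10
  substeps: 10
  dropout_rate: 0.0
  channel: red      # red = photoconverted, green = nonphotoconverted
  init: {kind: uniform, low: 0.0, high: 80.0}

# Initial condition used when `validate` re-simulates the fitted models.
validate:
  init: {kind: uniform, low: 0.0, high: 80.0}

# Track files consumed by `fit`/`validate` when none are given as
# arguments (paths relative to the working directory).
fit:
  tracks: []
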