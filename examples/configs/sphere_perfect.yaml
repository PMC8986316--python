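# Spherical cell, perfectly absorbing cortex: the baseline
# scale-invariant gradient (D = 1 um^2/s, v = 1 um/s, 1000 proteins).
geometry:
  shape: sphere
  R: 10.0
  epsilon_fraction: 0.05
physics:
  D: 1.0
  v: 1.0
  kon: null        # perfect absorption
  t_bound: null    # no detachment
simulation:
  N: 1000
  dt: 0.001
  T_total: 600.0
  burn_in: 150.0
  n_bins: 50
  seed: 0
  snapshot_interval: 0.5
output:
  directory: out_sphere
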