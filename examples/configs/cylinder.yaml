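# Cylindrical cell (radius 10 um, total length 60 um): the decay
# length of the gradient is R/2.405, independent of cell length.
geometry:
  shape: cylinder
  R: 10.0
  L: 30.0
  epsilon_fraction: 0.05
physics: {D: 1.0, v: 1.0, kon: null, t_bound: null}
simulation: {N: 1000, dt: 0.001, T_total: 900.0, burn_in: 300.0, n_bins: 60, seed: 0}
output: {directory: out_cylinder}
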