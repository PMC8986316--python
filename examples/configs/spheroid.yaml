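# Prolate spheroid (aspect ratio 2): interpolates sphere -> cylinder.
geometry:
  shape: spheroid
  R: 10.0
  a: 20.0
  epsilon_fraction: 0.05
physics: {D: 1.0, v: 1.0, kon: null, t_bound: null}
simulation: {N: 1000, dt: 0.001, T_total: 900.0, burn_in: 300.0, n_bins: 50, seed: 0}
output: {directory: out_spheroid}
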