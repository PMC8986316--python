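# Imperfect transport: bound proteins detach at rate 1/t_bound,
# flattening the gradient while preserving its scaling with R.
geometry: {shape: sphere, R: 10.0, epsilon_fraction: 0.05}
physics: {D: 1.0, v: 1.0, kon: null, t_bound: 1.0}
simulation: {N: 1000, dt: 0.001, T_total: 600.0, burn_in: 150.0, n_bins: 50, seed: 0}
output: {directory: out_detachment}
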