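# Reactive (partially absorbing) cortex, kon = 0.1 um/s: capture
# efficiency kon*R/D = 1, where scaling with cell size is lost.
geometry: {shape: sphere, R: 10.0, epsilon_fraction: 0.05}
physics: {D: 1.0, v: 1.0, kon: 0.1, t_bound: null}
simulation: {N: 1000, dt: 0.001, T_total: 900.0, burn_in: 300.0, n_bins: 50, seed: 0}
output: {directory: out_reactive}
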