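# Reduced-scale demo configuration for the synthetic bench.
# Fields mirror chronoglm.simulate.SimConfig; omitted fields keep the
# full study-design defaults (120 trials, TR 0.756 s, 72 ms RT SD, ...).
n_subjects: 6
n_sessions: 2
n_trials: 48
grid_shape: [8, 8, 8]
block_size: 2
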