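# Full factorial design: 4 models x 5 sample sizes x 3 error shapes x 4
# heteroskedasticity levels, minus the unattainable (n=25, severe) cells.
models: [1, 2, 3, 4]
ns: [25, 50, 100, 200, 500]
distributions: [normal, moderate, severe]
g_levels: [0, 0.5, 1, 2]
n_reps: 10000
B: 1000
seed: 12345
constrained_sampling: true
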