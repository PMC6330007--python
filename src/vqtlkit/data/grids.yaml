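# Default simulation grid for the ideal heteroskedastic model benchmark.
n: [300, 500, 1000]
pi_maf: [0.05, 0.2, 0.3]
beta: [0.0, 0.2, 0.5, 1.0]
log_alpha: [-0.2, -0.1, 0.0, 0.1, 0.2]
beta0: [0.0, 1.0]
sigma2: 1.0
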