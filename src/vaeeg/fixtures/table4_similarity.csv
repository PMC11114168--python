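band,printed_percent
delta,79.17
theta,79.17
alpha,70.83
beta,54.17
gamma,62.50
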