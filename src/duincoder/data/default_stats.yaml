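# Shipped z-score constants (reference experimental setup).
mean: [55.372, -0.004, 0.178, 0.070, -0.090, 0.003]
std: [19.734, 0.069, 0.145, 0.240, 0.470, 0.066]
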