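# 256-combination design clustered with complete linkage + SIMPROF
variant: four_osc
simulation: {}
n_trials: 200
levels: [1, 5, 9, 13]
alpha: 0.001
n_expected: 1000
n_pvalue: 999
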