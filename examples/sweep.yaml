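# Equal-weight coupling sweep of the four-oscillator model
variant: four_osc
simulation: {}
n_trials: 200
weight_min: 0.1
weight_max: 30.0
weight_step: 0.1
smoothing_window: 5
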