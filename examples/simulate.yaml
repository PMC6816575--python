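# One leading-following condition: 200 trials of 12 s
model:
  variant: four_osc
  i1: 1.7
  e1: 5.5
  i2: 4.1
  e2: 5.5
simulation:
  dt: 0.01
  sample_interval: 0.01
  noise_sd: 0.4335
n_trials: 200
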