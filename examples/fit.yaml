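# Reduced-scale fit of a synthetic mutual-adaptation target
variant: four_osc
target:
  preset: mutual_adaptation_1
simulation: {}
grid:
  coarse_min: 1.0
  coarse_max: 8.0
  coarse_step: 1.0
  refine_halfwidth: 0.4
  refine_step: 0.2
  trials_coarse: 50
  trials_refine: 50
  trials_final: 200
  dt_final: 0.01
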