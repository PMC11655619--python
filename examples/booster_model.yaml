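# Fast-waning pathogen under recurrent boosting.
# Infectious for ~4 days at constant transmission rate; immunity is lost
# after an Exp(8-day) immune period; boosters arrive every ~30 days
# (Gamma-distributed intervals).
infectiousness:
  family: constant
  beta: 0.5
  duration: {family: exponential, rate: 0.25}
susceptibility:
  kind: step
  recovery: {family: exponential, rate: 0.125}
vaccination: {family: gamma, shape: 4, scale: 7.5}
initial:
  i0: 0.1
  h_i: {family: stationary}
  h_s: {family: stationary}
numerics: {dt: 0.02, t_max: 150, k_sigma: 16}
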