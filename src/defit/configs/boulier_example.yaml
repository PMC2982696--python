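# Two-compartment exchange with Michaelis-Menten elimination, the classic
# worked example for differential elimination: x_1 exchanges with an
# unmeasured compartment x_2 and is cleared by a saturable route.
# Reference parameter values and bounds are package conventions (the model
# is used as an elimination benchmark, not as a recovery benchmark).
name: boulier_example
states: [x_1, x_2]
params: [k_12, k_21, k_e, V_e]
rhs:
  x_1: "-k_12*x_1 + k_21*x_2 - V_e*x_1/(k_e + x_1)"
  x_2: "k_12*x_1 - k_21*x_2"
init:
  x_1: 50.0
  x_2: 0.0
observed: [x_1]
ranking: [x_2, x_1]
bounds:
  k_12: [0.01, 2.0]
  k_21: [0.01, 1.0]
  k_e: [1.0, 20.0]
  V_e: [1.0, 40.0]
true_params:
  k_12: 0.5
  k_21: 0.3
  k_e: 7.0
  V_e: 20.0
time:
  start: 0.01
  stop: 1.0
  step: 0.01
et_threshold: 0.01
constraint_normalization: raw_sum
alpha: 0.1
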