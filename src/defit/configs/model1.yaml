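# Binding/dissociation of two molecules A + B <-> AB (mass action).
# Only the complex x_AB is measured; the reference curve is sampled on
# t = 0.01 .. 1.00 at step 0.01 (the T = 100 grid, t = 0 excluded).
name: model1
states: [x_A, x_B, x_AB]
params: [k_p, k_m]
rhs:
  x_A: "-k_p*x_A*x_B + k_m*x_AB"
  x_B: "-k_p*x_A*x_B + k_m*x_AB"
  x_AB: "k_p*x_A*x_B - k_m*x_AB"
init:
  x_A: 10.0
  x_B: 20.0
  x_AB: 0.0
observed: [x_AB]
# elimination ranking, highest (eliminated first) to lowest
ranking: [x_A, x_B, x_AB]
bounds:
  k_p: [0.0, 0.5]
  k_m: [0.0, 5.0]
true_params:
  k_p: 0.05
  k_m: 0.5
hist_bin_width:
  k_p: 0.01
  k_m: 0.1
time:
  start: 0.01
  stop: 1.0
  step: 0.01
et_threshold: 0.01
constraint_normalization: raw_sum
alpha: 0.1
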