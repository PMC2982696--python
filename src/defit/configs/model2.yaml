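# Linear activation cascade: a pool P feeds x_2, x_3, x_4, which each
# activate x_1 linearly; x_1 is degraded through two channels (k_e1, k_e2).
# Only x_1 is measured, on the same T = 100 grid as model1.
# P(0) = 100.0 is a repository convention (documented in docs/methods.md).
name: model2
states: [P, x_2, x_3, x_4, x_1]
params: [k_21, k_31, k_41, k_p2, k_p3, k_p4, k_e1, k_e2]
rhs:
  P: "-(k_p2 + k_p3 + k_p4)*P"
  x_2: "k_p2*P - k_21*x_2"
  x_3: "k_p3*P - k_31*x_3"
  x_4: "k_p4*P - k_41*x_4"
  x_1: "k_21*x_2 + k_31*x_3 + k_41*x_4 - k_e1*x_1 - k_e2*x_1"
init:
  P: 100.0
  x_2: 130.0
  x_3: 80.0
  x_4: 170.0
  x_1: 10.0
observed: [x_1]
ranking: [P, x_4, x_3, x_2, x_1]
bounds:
  k_21: [0.0, 50.0]
  k_31: [0.0, 70.0]
  k_41: [0.0, 110.0]
  k_p2: [0.0, 30.0]
  k_p3: [0.0, 40.0]
  k_p4: [0.0, 100.0]
  k_e1: [0.0, 50.0]
  k_e2: [0.0, 30.0]
true_params:
  k_21: 5.0
  k_31: 7.0
  k_41: 11.0
  k_p2: 3.0
  k_p3: 4.0
  k_p4: 10.0
  k_e1: 5.0
  k_e2: 3.0
hist_bin_width:
  k_21: 1.0
  k_31: 1.0
  k_41: 1.0
  k_p2: 1.0
  k_p3: 1.0
  k_p4: 1.0
  k_e1: 1.0
  k_e2: 1.0
time:
  start: 0.01
  stop: 1.0
  step: 0.01
et_threshold: 0.001
constraint_normalization: pareto_balanced
alpha: 0.9999999
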