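# defit eliminated system v1
model: model1
observed: x_AB
ranking: x_A,x_B,x_AB
order: x_AB=1
substitution: x_B = -x_AB + 20
solution: x_A = -x_AB + 10
equation x_A: x_A + x_AB - 10
equation -: k_m*x_AB - k_p*x_AB**2 + 30*k_p*x_AB - 200*k_p + x_AB__d1
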