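# defit eliminated system v1
model: boulier_example
observed: x_1
ranking: x_2,x_1
order: x_1=2
solution: x_2 = (V_e*x_1 + k_12*k_e*x_1 + k_12*x_1**2 + k_e*x_1__d1 + x_1*x_1__d1)/(k_21*(k_e + x_1))
prolongation x_2: (V_e*x_1 + k_12*x_1*(k_e + x_1) - k_21*x_2*(k_e + x_1) + x_1__d1*(k_e + x_1))/(k_e + x_1)
equation x_2: V_e*x_1 + k_12*k_e*x_1 + k_12*x_1**2 - k_21*k_e*x_2 - k_21*x_1*x_2 + k_e*x_1__d1 + x_1*x_1__d1
equation -: V_e*k_21*k_e*x_1 + V_e*k_21*x_1**2 + V_e*k_e*x_1__d1 + k_12*k_e**2*x_1__d1 + 2*k_12*k_e*x_1*x_1__d1 + k_12*x_1**2*x_1__d1 + k_21*k_e**2*x_1__d1 + 2*k_21*k_e*x_1*x_1__d1 + k_21*x_1**2*x_1__d1 + k_e**2*x_1__d2 + 2*k_e*x_1*x_1__d2 + x_1**2*x_1__d2
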