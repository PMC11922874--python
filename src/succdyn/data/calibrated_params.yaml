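kind: calibrated
v_Gly1: 2.32
k_Gly1: 39.99
v_Gly2: 1.78
k_Gly2: 1.24e-10
v_Gly3: 1.08
k_Gly3: 9.9e-05
v_P1: 0.27
k_P1: 2.65e-05
v_P2: 0.12
k_P2: 0.000671
v_P3: 0.2
k_P3: 0.00037
v_G: 0.0861
k_G: 0.000189
G3P_max: 0.000497
PEP_max: 0.00047
P_max: 0.000454
eta_X: 0.83
n_X: 1.57
n_SA: 1.49
n_AA: 6.15
n_FA: 3.01
a1: 0.88
k1: 53.39
G_mid1: 51.49
a2: 0.18
k2: 10.13
R_mid: 1.2
k3: 22.06
ATP_mid: 0.36
k4: 410.0
G_mid2: 2.02
k5: 13.84
SA_mid: 23.05
k6: 11.04
AA_mid: 0.45
k7: 8.67
FA_mid: 1.08
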