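kind: calibrated
v_Gly1: 1.5
k_Gly1: 1.0
v_Gly2: 1.0
k_Gly2: 1.0e-05
v_Gly3: 1.0
k_Gly3: 1.0e-05
v_P1: 1.0
k_P1: 1.0e-05
v_P2: 1.0
k_P2: 1.0e-05
v_P3: 1.0
k_P3: 1.0e-05
v_G: 0.5
k_G: 1.0e-05
G3P_max: 0.0005
PEP_max: 0.0005
P_max: 0.0005
eta_X: 0.7
n_X: 1.0
n_SA: 1.2
n_AA: 5.0
n_FA: 2.5
a1: 1.0
k1: 200.0
G_mid1: 5.0
a2: 1.0
k2: 200.0
R_mid: 5.0
k3: 15.0
ATP_mid: 0.25
k4: 300.0
G_mid2: 2.5
k5: 13.93
SA_mid: 20.0
k6: 5.0
AA_mid: 2.0
k7: 5.0
FA_mid: 1.0
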