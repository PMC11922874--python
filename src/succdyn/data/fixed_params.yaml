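kind: fixed
MW_X: 24.55
MW_G: 180.16
MW_G3P: 170.06
MW_PEP: 168.04
MW_P: 88.06
MW_SA: 118.09
MW_AA: 60.05
MW_FA: 46.03
s_ATP: 1.0
nu_G3P: 2.0
nu_P: 1.0
nu_Pyr: 1.0
nu_X: 3.0
nu_SA: 1.0
nu_AA: 1.0
nu_FA: 1.0
nu_ATP1: 2.0
nu_ATP2: 1.0
nu_ATP3: 1.0
nu_ATP4: 1.0
nu_ATP5: 1.0
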