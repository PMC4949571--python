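reaction,isotope,k0,k0_err,dV_act,dV_err,dBeta_act,dBeta_err
hydride,H,2.300000e+06,9.000000e+04,6.6,2.2,4.7,2.0
hydride,D,1.030000e+06,2.000000e+04,5.0,1.2,9.5,1.3
proton,H,2.350000e+04,4.000000e+02,1.7,1.0,-4.7,1.1
proton,D,1.080000e+04,3.000000e+02,7.5,2.3,4.9,2.5
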