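reaction,isotope,pressure_bar,temperature_K,k_obs,k_err
hydride,H,1,298.15,2.260000e+06,2.100000e+05
hydride,H,250,298.15,2.110000e+06,1.800000e+05
hydride,H,500,298.15,2.120000e+06,1.700000e+05
hydride,H,750,298.15,2.050000e+06,1.200000e+05
hydride,H,1000,298.15,2.010000e+06,2.000000e+05
hydride,H,1250,298.15,1.800000e+06,1.200000e+05
hydride,H,1500,298.15,1.990000e+06,2.500000e+05
hydride,H,1750,298.15,1.850000e+06,2.000000e+05
hydride,H,2000,298.15,2.020000e+06,1.500000e+05
hydride,D,1,298.15,1.010000e+06,1.200000e+05
hydride,D,250,298.15,1.030000e+06,1.300000e+05
hydride,D,500,298.15,9.900000e+05,1.700000e+05
hydride,D,750,298.15,9.900000e+05,1.200000e+05
hydride,D,1000,298.15,1.020000e+06,6.000000e+04
hydride,D,1250,298.15,1.110000e+06,2.100000e+05
hydride,D,1500,298.15,1.140000e+06,1.700000e+05
hydride,D,1750,298.15,1.290000e+06,2.600000e+05
hydride,D,2000,298.15,1.560000e+06,3.100000e+05
proton,H,1,298.15,2.390000e+04,1.800000e+03
proton,H,250,298.15,2.310000e+04,2.300000e+03
proton,H,500,298.15,2.110000e+04,2.100000e+03
proton,H,750,298.15,2.100000e+04,1.000000e+03
proton,H,1000,298.15,2.020000e+04,8.000000e+02
proton,H,1250,298.15,1.890000e+04,9.000000e+02
proton,H,1500,298.15,1.710000e+04,1.200000e+03
proton,H,1750,298.15,1.550000e+04,1.700000e+03
proton,H,2000,298.15,1.360000e+04,2.600000e+03
proton,D,1,298.15,1.100000e+04,5.000000e+02
proton,D,250,298.15,9.600000e+03,8.000000e+02
proton,D,500,298.15,9.300000e+03,7.000000e+02
proton,D,750,298.15,9.100000e+03,1.400000e+03
proton,D,1000,298.15,9.000000e+03,1.100000e+03
proton,D,1250,298.15,8.600000e+03,1.100000e+03
proton,D,1500,298.15,8.100000e+03,9.000000e+02
proton,D,1750,298.15,8.300000e+03,1.000000e+03
proton,D,2000,298.15,9.900000e+03,1.200000e+03
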