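system,kie0,kie0_err,ddH,ddH_err,ddS,ddS_err,ddV,ddV_err,ddBeta,ddBeta_err
MR,6.8,0.1,7.2,1.5,20,13,-8.8,1.3,4.8,1.1
PETNR-NADPH,7.0,0.1,6.5,2.8,7,6,0.6,6.1,2.6,6.5
PETNR-NADH,8.1,0.1,-1.1,2.1,-20,6,5.4,3.0,-1.9,3.2
AADH,12.8,0.8,6.8,3.9,1.6,13.5,1.9,2.7,0.9,2.3
POR-hydride,2.2,0.1,8.2,0.6,21.2,3.3,1.6,3.3,-4.8,3.3
POR-proton,2.2,0.1,9.8,0.8,26.5,1.2,-5.8,3.3,-9.6,3.6
Asc-FeCyn,5.1,0.1,1.1,0.9,-10,3,7.5,0.4,0,0
Asc-FeCyn-TEA,9.9,0.1,6.1,0.9,2,3,1.8,1.4,0,0
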