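parameter,season,min,max,mean,sd
pH,dry,7.01,8.13,7.57,0.25
pH,wet,7.04,8.62,7.69,0.33
TDS,dry,248,1040,527.75,196.03
TDS,wet,165,993,495.29,194.41
TH,dry,88,711,373.64,153.45
TH,wet,70,633,344.32,147.37
Ca,dry,22.3,194,87.84,39.44
Ca,wet,18.6,170,80.07,35.88
Na,dry,19.1,118,49.58,21.69
Na,wet,10.2,110,46.65,21.62
Mg,dry,7.89,56.6,37.48,13.98
Mg,wet,5.74,56.2,35.04,14.58
K,dry,0.46,3.34,1.95,0.63
K,wet,0.44,3.11,1.86,0.56
Fe,dry,0.02,16,0.19,0.41
Fe,wet,0.01,0.15,0.02,0.03
HCO3,dry,200,587,327.89,90.83
HCO3,wet,110,563,318.86,96.26
SO4,dry,35.9,162,79.88,30.58
SO4,wet,30.9,165,77.41,31.91
Cl,dry,12.1,154,76.17,47.64
Cl,wet,7.34,155,69.67,46.44
NO3_N,dry,0.258,22.6,6.36,6.21
NO3_N,wet,0.018,20.3,5.16,5.77
F,dry,0.135,0.753,0.32,0.10
F,wet,0.087,0.795,0.34,0.12
NO2_N,dry,0.0003,0.0003,0.0003,0.00
NO2_N,wet,0.0003,0.0142,0.0022,0.00
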