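study,pH,TDS,TH,Ca,Na,Mg,K,Fe,HCO3,SO4,Cl,NO3_N,F,NO2_N
study01,0.013,0.038,0.056,0.016,0.023,0.016,,,0.015,0.021,0.027,0.136,0.375,0.184
study02,0.083,0.104,0.042,0.042,0.083,0.042,0.021,0.083,0.021,0.104,0.104,0.083,0.083,
study03,0.032,0.063,0.063,0.048,0.063,0.048,,0.079,0.016,0.048,0.063,0.079,,0.079
study04,0.041,0.068,0.041,,,,,0.041,,0.068,0.068,0.068,0.068,0.054
study05,0.069,0.069,0.023,,,,,0.023,,0.069,0.068,0.114,,0.114
study06,0.070,0.040,0.138,0.076,0.053,0.127,,,0.191,0.058,0.063,0.038,0.098,0.024
study07,0.093,0.080,0.096,,0.120,,,0.134,,0.098,0.082,0.375,0.121,0.360
study08,0.143,0.176,0.071,0.071,0.107,0.071,0.071,,0.071,0.107,0.107,,,
study09,0.080,0.110,0.060,0.060,0.080,0.060,,,0.020,0.080,0.110,0.110,0.110,
study10,0.103,0.064,,0.026,0.077,0.026,0.026,,0.077,0.051,0.077,,0.128,
study11,0.071,0.071,0.071,0.048,0.071,0.048,0.048,,0.048,0.095,0.095,0.119,0.119,
study12,0.050,0.050,,0.020,0.040,0.020,0.020,,0.020,0.070,0.100,,,
study13,0.114,0.114,,0.057,0.086,0.057,0.057,,0.029,,0.114,0.143,,
study14,0.093,0.116,0.070,,0.047,0.023,0.047,,0.070,0.093,0.070,0.116,0.116,
study15,0.103,0.172,,0.069,0.103,0.069,0.034,,0.069,0.103,0.103,0.172,,
study16,0.068,0.114,0.045,0.068,0.114,0.068,0.045,,0.023,0.114,0.114,0.114,0.114,
study17,0.110,,,0.060,0.060,0.060,0.030,,0.080,0.110,0.080,0.140,0.110,
study18,0.031,0.031,0.031,0.031,0.063,0.031,0.031,0.094,0.031,0.031,0.031,0.063,0.063,
study19,0.070,,0.023,,0.023,,,,,0.070,0.070,0.116,,0.116
study20,0.069,,0.063,0.063,0.070,,,0.084,,,0.070,0.070,0.126,
study21,0.094,,,0.094,0.063,0.063,0.063,0.125,0.063,0.125,0.094,,,
study22,0.135,0.108,0.054,0.054,,0.027,,0.135,,0.108,0.081,0.135,0.108,
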