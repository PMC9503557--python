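patient_id,angle_class,displacement,bite,age_group,gender,face_total,nose,upper_cheek,lower_cheek,upper_lip,lower_lip,both_lips,chin
P001,III,lt5mm,neutral,lt30,female,79.52569642,88.40028957,91.4513592,80.05329839,87.42838717,78.68553389,76.11316524,92.61827899
P002,II,lt5mm,deep,30to40,female,83.9992184,92.65621118,81.48573183,77.22238589,83.56695683,73.1775294,73.42607471,87.91410973
P003,III,lt5mm,neutral,lt30,male,87.0941176,100,93.38643409,78.69325896,83.13558896,81.05989193,82.02272429,73.19833731
P004,II,lt5mm,deep,lt30,male,83.28790023,88.67310727,83.0156141,77.7590758,93.34212742,70.01362777,79.75440549,79.2317098
P005,III,gt5mm,neutral,lt30,male,79.78527845,89.50422565,93.02695401,80.0318364,85.97158118,78.44689231,81.62611415,74.12481357
P006,III,gt5mm,open,lt30,male,82.41035627,92.82161578,86.61801187,78.49893264,89.16672143,76.97572832,76.04282023,68.99424634
P007,II,gt5mm,deep,gt40,male,84.51691822,93.97205317,93.11596434,78.80031314,87.86483826,78.49447645,77.36776483,79.8795386
P008,II,lt5mm,open,lt30,male,84.21086309,91.29437574,90.52380483,74.48570126,86.23541919,82.51603323,76.00382789,87.3342394
P009,III,gt5mm,deep,gt40,female,76.54373143,91.17627868,83.85266024,76.77261629,85.96815612,80.93778189,76.45343253,88.18847962
P010,III,lt5mm,deep,gt40,female,80.95391413,94.80985182,94.996595,86.6162302,90.52033037,70.41929237,80.78163167,83.30981717
P011,II,gt5mm,deep,lt30,female,83.22567511,94.07963055,95.76682862,77.31506713,86.79252958,68.24531368,76.86810153,84.23720053
P012,II,lt5mm,open,lt30,female,89.6645111,87.86529667,89.73678038,75.78362485,87.39422541,78.26755624,81.42426516,92.52245292
P013,II,gt5mm,open,lt30,female,87.61235401,91.68327473,88.90433491,81.34930533,88.08888623,70.93995034,81.3590237,88.63050649
P014,III,gt5mm,neutral,lt30,female,80.90342555,92.14114739,89.36053214,85.6290888,92.70603328,74.95037845,88.10064395,88.19199697
P015,III,lt5mm,neutral,30to40,female,83.67352409,87.78206151,86.09939071,74.18390279,90.7220439,78.35890991,74.42884382,87.78615284
P016,II,gt5mm,neutral,lt30,male,83.64052179,93.0393564,94.39434704,79.16591261,89.53040107,68.4248106,83.55160951,82.15360105
P017,III,lt5mm,deep,gt40,female,85.20850543,88.56817409,87.82843227,77.47178978,85.74571443,66.56007818,79.64204815,91.22162259
P018,II,lt5mm,neutral,lt30,male,84.97840176,95.88826683,89.79523835,72.9559221,82.47212512,76.03719608,79.94388108,84.21026919
P019,III,gt5mm,deep,30to40,male,83.33352942,92.77098365,86.82681439,82.93970684,91.79811973,75.17754356,74.20054471,82.8628188
P020,III,lt5mm,neutral,30to40,male,75.83642702,92.35722594,87.4957076,79.90622433,91.86578854,74.01678771,78.15922475,77.82852657
P021,II,lt5mm,deep,lt30,male,86.3867202,89.63588659,84.88909939,80.28576738,87.4371664,75.15413906,82.97278905,84.04443506
P022,III,gt5mm,deep,30to40,female,74.24718353,91.5255607,95.02827725,76.99075411,90.16753537,71.55793757,79.67008651,85.26301169
P023,II,gt5mm,open,30to40,female,76.85868422,84.00901483,89.38364971,81.81913665,91.12577222,68.94602237,80.32421748,92.3753827
P024,III,gt5mm,open,gt40,male,79.78209249,87.47437012,93.86368647,77.8428106,91.32473781,74.3333806,78.83713328,76.91579671
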