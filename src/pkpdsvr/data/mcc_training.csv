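time_h,gallic_acid,5_HMF,3_H_2_M_4_P,oxpaeoniflorin,3_8_D_2_MC,paeoniflorin,benzoic_acid,methyl_paraben,quercetin,paeonol,TXB2,6_keto_PGF1a
0.08,109.76,145.36,7.45,0.00,19.63,86.97,7.81,0.55,39.96,2.78,0.85,0.50
0.25,114.10,211.68,12.45,0.00,19.13,101.35,4.60,1.57,49.51,3.40,1.47,0.47
0.5,161.24,309.53,22.32,0.00,49.98,179.54,9.33,2.63,83.47,3.60,1.88,1.05
0.75,247.45,358.91,9.16,0.00,55.01,62.49,10.86,2.85,102.44,5.11,1.12,0.43
1,223.14,422.25,6.69,0.00,21.02,48.45,11.33,2.59,130.29,3.23,1.44,0.82
2,133.16,455.35,2.46,0.00,19.40,53.92,18.96,0.72,150.92,3.19,1.69,1.80
3,88.43,269.97,2.01,0.00,16.33,63.23,19.22,0.64,207.95,1.86,2.46,0.83
4,44.24,185.84,1.60,0.00,7.12,63.70,19.85,0.89,100.01,2.50,2.42,0.48
6,40.66,144.41,1.30,0.00,6.82,58.14,24.68,0.73,123.57,3.68,1.52,1.66
8,36.64,30.68,0.89,0.00,7.03,60.58,22.36,0.33,141.34,3.60,2.93,1.02
10,28.99,18.82,0.54,0.00,6.64,47.74,14.47,0.30,94.21,2.49,1.91,-0.60
12,27.63,6.83,0.45,0.00,4.79,15.01,9.45,0.19,62.31,2.40,0.87,4.08
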