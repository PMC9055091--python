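time_h,gallic_acid,5_HMF,3_H_2_M_4_P,oxpaeoniflorin,3_8_D_2_MC,paeoniflorin,benzoic_acid,methyl_paraben,quercetin,paeonol,TXB2,6_keto_PGF1a
0.08,78.06,22.89,3.18,0.96,65.06,84.19,17.98,0.69,89.32,2.97,1.12,0.05
0.25,88.72,33.84,3.67,1.21,80.75,114.71,24.20,1.61,120.70,3.35,-0.07,0.63
0.5,102.00,36.25,4.11,1.23,107.34,184.15,35.60,1.92,248.61,4.42,-0.38,0.60
0.75,133.14,51.90,2.52,1.27,120.85,75.15,39.79,3.13,256.99,6.02,0.41,0.89
1,113.30,64.61,2.15,1.46,78.55,53.40,54.21,1.43,270.83,2.20,0.89,1.26
2,96.66,119.27,1.44,1.55,37.11,53.62,51.24,0.50,301.84,4.14,-0.10,-0.53
3,73.65,103.69,1.08,1.50,36.57,35.84,65.02,0.67,412.90,4.77,0.63,-0.02
4,63.71,76.60,1.36,1.73,22.61,52.76,127.25,0.56,451.64,3.00,-0.02,1.06
6,46.25,58.06,0.75,1.02,23.00,52.06,69.82,0.60,219.12,2.11,-0.82,1.19
8,45.90,22.82,0.97,1.04,17.96,44.03,71.83,0.30,287.27,1.33,0.94,0.92
10,42.48,15.21,0.90,0.96,11.36,36.26,61.01,0.27,351.53,1.05,0.99,0.34
12,31.11,9.97,0.72,0.90,5.61,22.03,31.37,0.17,206.96,0.94,0.55,2.04
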