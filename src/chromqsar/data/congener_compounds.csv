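compound_id,series,substituent,mw,tpsa,alpha,log_p,log_Kp,log_KaHSA,log_BB,caco2_e06,fu_brain,log_kw_iam,log_kw_ods
1,I,"H",256.3,48.27,29.3,2.089,-6.061,4.8,0.23,187,0.52,0.76,1.59
2,I,"4-CH3",270.33,48.27,31.06,2.701,-5.711,4.86,0.423,217,0.32,1.05,2.01
3,I,"2-Cl",290.75,48.27,31.13,2.608,-5.8,5.09,0.339,215,0.33,0.65,1.42
4,I,"3-Cl",290.75,48.27,31.13,2.757,-5.645,5.07,0.384,221,0.28,1.49,2.38
5,I,"4-Cl",290.75,48.27,31.13,2.559,-5.817,5.16,0.328,208,0.38,1.39,2.32
6,I,"3,4-Cl2",325.19,48.27,32.95,3.25,-5.37,5.44,0.473,230,0.21,1.67,2.68
7,II,"H",282.22,48.27,25.85,1.661,-6.021,4.96,0.102,196,0.44,0.94,1.92
8,II,"2-CH3",296.25,48.27,27.61,2.273,-5.672,5.01,0.29,220,0.27,0.76,1.81
9,II,"4-CH3",296.25,48.27,27.61,2.273,-5.672,5.01,0.29,220,0.27,1.25,2.16
10,II,"2-OCH3",312.25,57.5,28.16,1.647,-6.245,5.03,0.063,195,0.43,0.67,1.65
11,II,"2-Cl",316.67,48.27,27.68,2.151,-5.762,5.29,0.211,220,0.27,0.88,1.86
12,II,"3-Cl",316.67,48.27,27.68,2.345,-5.603,5.31,0.264,221,0.26,1.66,2.43
13,II,"4-Cl",316.67,48.27,27.68,2.131,-5.778,5.33,0.194,218,0.29,1.58,2.4
14,II,"3,4-Cl2",351.11,48.27,29.5,2.828,-5.332,5.64,0.345,235,0.14,2.29,2.96
15,III,"H",286.29,74.57,30.27,0.931,-6.989,5.04,-0.243,134,0.73,0.48,1.21
16,III,"4-CH3",300.31,74.57,32.02,1.548,-6.64,5.07,-0.051,169,0.59,1.93,2.8
17,III,"3-Cl",320.73,74.57,32.09,1.605,-6.575,5.25,-0.09,179,0.55,1.73,2.62
18,III,"4-Cl",320.73,74.57,32.09,1.401,-6.746,5.35,-0.151,170,0.59,1.12,1.92
19,III,"3,4-Cl2",355.18,74.57,33.91,2.132,-6.3,5.6,0.0,202,0.42,3.36,3.24
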