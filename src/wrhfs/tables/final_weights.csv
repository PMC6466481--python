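order,feature,weight,contribution,cumulative,weight01
1,Age,176.31,0.13,0.13,1
2,α-HBD,88.36,0.06,0.19,0.42
3,SCr,83.02,0.06,0.25,0.38
4,LDH,70.59,0.05,0.30,0.30
5,Height,70.32,0.05,0.35,0.30
6,TBIL,66.18,0.05,0.39,0.27
7,CK,59.22,0.04,0.44,0.22
8,Apo-B,55.61,0.04,0.48,0.20
9,CK-MB,54.09,0.04,0.51,0.19
10,Alb,48.60,0.03,0.55,0.15
11,AST,47.49,0.03,0.58,0.15
12,GGP,45.36,0.03,0.61,0.13
13,DBIL,40.76,0.03,0.64,0.10
14,Glu,39.35,0.03,0.67,0.09
15,Gender,37.99,0.03,0.70,0.08
16,ALP,36.26,0.03,0.72,0.07
17,Apo-A1,35.60,0.03,0.75,0.07
18,TP,35.22,0.03,0.77,0.06
19,Ca,34.34,0.02,0.80,0.06
20,TC,34.34,0.02,0.82,0.06
21,BMI,33.90,0.02,0.85,0.06
22,HDL,33.16,0.02,0.87,0.05
23,BUN,32.92,0.02,0.89,0.05
24,PI,32.61,0.02,0.92,0.05
25,TG,32.37,0.02,0.94,0.05
26,UA,30.70,0.02,0.96,0.03
27,LDL,27.46,0.02,0.98,0.01
28,ALT,25.56,0.02,1.00,0
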