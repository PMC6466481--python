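feature,sd,C,q,accuracy,contribution,sd01,contribution01,weight
CK,0.21,16,0.5,56.1,,1.00,1.00,
LDH,0.21,64,0.5,57.1,1.00,0.99,0.30,1.00
α-HBD,0.19,128,8.0,58.6,1.52,0.91,0.37,1.52
Height,0.17,8,8.0,57.3,-1.26,0.81,0.00,-1.26
ALP,0.15,2,4.0,58.8,1.52,0.72,0.37,1.52
UA,0.10,1,8.0,58.6,-0.25,0.48,0.13,-0.25
SCr,0.09,16,4.0,61.9,3.28,0.41,0.60,3.28
GGP,0.08,16,2.0,61.6,-0.25,0.40,0.13,-0.25
TP,0.08,2,8.0,61.6,0.00,0.37,0.17,0.00
AGE,0.08,64,1.0,67.9,6.31,0.36,1.00,6.31
ALT,0.07,128,1.0,67.6,-0.38,0.31,0.12,-0.38
AST,0.06,64,1.0,67.9,0.38,0.27,0.22,0.38
CK-MB,0.05,128,0.2,69.2,1.26,0.23,0.33,1.26
Alb,0.05,128,0.1,69.6,0.38,0.22,0.22,0.38
TBIL,0.04,256,0.5,72.1,2.53,0.16,0.50,2.53
BMI,0.03,64,0.3,72.7,0.63,0.12,0.25,0.63
Glu,0.01,128,0.3,72.7,0.00,0.04,0.17,0.00
DBIL,0.01,64,0.5,73.1,0.38,0.04,0.22,0.38
BUN,0.01,64,0.5,73.0,-0.13,0.03,0.15,-0.13
TC,0.01,64,0.5,73.2,0.25,0.02,0.20,0.25
LDL,0.01,128,1.0,73.0,-0.25,0.02,0.13,-0.25
TG,0.00,128,1.0,72.9,-0.13,0.02,0.15,-0.13
Gender,0.00,128,1.0,73.0,0.13,0.00,0.18,0.13
Ca,0.00,64,0.5,73.0,0.00,0.00,0.17,0.00
Apo-A1,0.00,128,1.0,73.2,0.25,0.00,0.20,0.25
HDL,0.00,128,1.0,73.1,-0.13,0.00,0.15,-0.13
Apo-B,0.00,128,1.0,73.1,0.00,0.00,0.17,0.00
PI,0.00,128,1.0,73.0,-0.13,0.00,0.15,-0.13
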