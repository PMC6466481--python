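order,feature,std,relief,infogain,weight_sum
1,α-HBD,0.9123,1.0000,0.0001,1.9124
2,GGP,0.4000,0.0657,0.0498,0.5156
3,Alb,0.2198,0.0592,0.0211,0.3001
4,LDL,0.0197,0.0026,0.0236,0.0459
5,TG,0.0156,0.0002,0.0001,0.0159
6,HDL,0.0032,0.0000,0.0010,0.0042
7,ALT,0.3120,0.0055,0.1141,0.4316
8,AST,0.2734,0.0366,0.0985,0.4085
9,SCr,0.4142,0.0637,0.0638,0.5417
10,CK,1.0000,0.5919,0.0549,1.6468
11,CK-MB,0.2303,0.0190,0.1657,0.4150
12,ALP,0.7239,0.0509,0.1051,0.8799
13,AGE,0.3574,0.0503,1.0000,1.4077
14,BUN,0.0296,0.0005,0.0845,0.1146
15,UA,0.4817,0.0024,0.0037,0.4878
16,LDH,0.9884,0.9582,0.0788,2.0254
17,Height,0.8145,0.4240,0.1235,1.3621
18,BMI,0.1171,0.0011,0.2146,0.3328
19,Gender,0.0049,0.0000,0.1349,0.1398
20,Ca,0.0040,0.0000,0.0000,0.0040
21,PI,0.0000,0.0001,0.0812,0.0813
22,Glu,0.0430,0.0009,0.4154,0.4593
23,Apo-A1,0.0036,0.0001,0.4525,0.4562
24,Apo-B,0.0013,0.0001,0.6987,0.7000
25,DBIL,0.0364,0.0003,0.2629,0.2996
26,TC,0.0248,0.0000,0.0382,0.0630
27,TBIL,0.1633,0.0323,0.5188,0.7143
28,TP,0.3667,0.0946,0.0417,0.5029
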