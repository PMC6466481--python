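feature,c_std,c_relief,c_infogain,d_std,d_relief,d_infogain
α-HBD,0.9123,1.0000,0.0001,1.6654,1.0000,6.2282
GGP,0.4000,0.0657,0.0498,2.8987,2.5000,5.1229
Alb,0.2198,0.0592,0.0211,4.9488,3.4428,5.8159
LDL,0.0197,0.0026,0.0236,6.5655,6.2714,5.5703
TG,0.0156,0.0002,0.0001,6.7155,7.8856,6.3685
HDL,0.0032,0.0000,0.0010,7.4155,9.4571,6.0966
ALT,0.3120,0.0055,0.1141,4.1821,6.0714,3.7369
AST,0.2734,0.0366,0.0985,4.3988,5.0000,4.0439
SCr,0.4142,0.0637,0.0638,2.7654,3.0857,4.8422
CK,1.0000,0.5919,0.0549,1.0000,1.6571,4.9562
CK-MB,0.2303,0.0190,0.1657,4.7321,5.8428,2.4474
ALP,0.7239,0.0509,0.1051,2.0320,3.6428,3.8158
AGE,0.3574,0.0503,1.0000,4.0654,4.6428,1.0000
BUN,0.0296,0.0005,0.0845,6.2321,7.3999,4.1930
UA,0.4817,0.0024,0.0037,2.1654,6.5428,5.9299
LDH,0.9884,0.9582,0.0788,1.2987,1.6571,4.5878
Height,0.8145,0.4240,0.1235,1.6654,1.7714,3.6492
BMI,0.1171,0.0011,0.2146,5.6988,6.8857,2.3070
Gender,0.0049,0.0000,0.1349,6.8988,9.2142,2.6492
Ca,0.0040,0.0000,0.0000,7.0655,9.7142,6.5264
PI,0.0000,0.0001,0.0812,7.7322,8.1285,4.3509
Glu,0.0430,0.0009,0.4154,5.8655,7.1428,2.0614
Apo-A1,0.0036,0.0001,0.4525,7.2655,8.4142,1.8246
Apo-B,0.0013,0.0001,0.6987,7.5822,8.7285,1.4386
DBIL,0.0364,0.0003,0.2629,6.0821,7.6285,2.3070
TC,0.0248,0.0000,0.0382,6.4322,8.9571,5.4387
TBIL,0.1633,0.0323,0.5188,5.4488,5.3857,1.7018
TP,0.3667,0.0946,0.0417,3.0654,2.0428,5.2808
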