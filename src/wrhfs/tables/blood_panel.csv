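name,full_name,unit,value_kind
α-HBD,Alpha hydroxybutyric dehydrogenase,IU/L,integer
GGP,Gamma glutamyl transpeptidase,IU/L,integer
LDH,Lactate dehydrogenase,mmol/L,real
LDL,Low-density lipoprotein,mmol/L,real
HDL,High-density lipoprotein,mmol/L,real
BUN,Blood urea nitrogen,mmol/L,real
UA,Uric acid,umol/L,integer
TC,Total cholesterol,mmol/L,real
TBIL,Total bilirubin,umol/L,real
TP,Total protein,g/L,integer
TG,Triglyceride,mmol/L,real
Alb,Albumin,g/L,integer
DBIL,Direct bilirubin,umol/L,real
ALP,Alkaline phosphatase,IU/L,integer
PI,Serum phosphorus,mmol/L,real
SCr,Serum creatinine,umol/L,integer
CK,Creatine kinase,IU/L,integer
CK-MB,Creatine kinase isoenzyme,IU/L,integer
Glu,Glucose,mmol/L,real
ALT,Alanine aminotransferase,IU/L,integer
AST,Aspartate aminotransferase,IU/L,integer
Apo-A1,Apolipoprotein A1,g/L,real
Apo-B,Apolipoprotein B,g/L,real
Ca,Serum calcium,mmol/L,real
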