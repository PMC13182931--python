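variable,unit,p
Age,year,<0.001
Gender,-,0.34
Height,cm,0.81
Weight,kg,<0.01
BMI,-,0.04
Albumin,g/l,<0.001
Diab,-,<0.001
SBP,mmHg,0.19
DBP,mmHg,<0.001
WBC,10^9/l,0.58
Hb,g/l,<0.001
Urea,mmol/l,<0.001
Scr,umol/l,<0.001
K,mmol/l,<0.01
Na,mmol/l,<0.01
Cl,mmol/l,0.48
Ca,mmol/l,<0.001
P,mmol/l,<0.001
Hs-CRP,mg/l,<0.01
Glucose,mmol/l,<0.001
CO2CP,mmol/l,<0.001
GFR,ml/min,0.14
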