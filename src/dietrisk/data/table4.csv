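nutrient,unit,hr_all,ci_all,p_all,hr_low,ci_low,p_low,hr_medium,ci_medium,p_medium,hr_high,ci_high,p_high
Water,100 g/d,0.95,0.92-0.99,<0.01,0.98,0.93-1.04,0.56,0.97,0.91-1.03,0.34,0.86,0.77-0.95,<0.01
Protein,g/d,0.97,0.96-0.98,<0.001,0.98,0.96-1.00,0.09,0.98,0.96-1.01,0.15,0.94,0.91-0.97,<0.001
Fat,10 g/d,0.82,0.74-0.92,<0.001,0.97,0.81-1.16,0.72,0.84,0.71-1.01,0.06,0.58,0.44-0.76,<0.001
Carbohydrate,g/d,0.99,0.99-1.00,<0.001,0.99,0.99-1.00,0.05,0.99,0.99-1.00,0.04,0.99,0.98-1.00,<0.01
Calories,10 kcal/d,0.99,0.98-0.99,<0.001,0.99,0.98-1.00,0.07,0.99,0.99-1.00,0.09,0.98,0.96-0.99,<0.001
Df,g/d,0.90,0.86-0.95,<0.001,0.93,0.86-1.00,0.06,0.92,0.85-1.00,0.06,0.80,0.70-0.90,<0.001
K,10 mg/d,0.99,0.99-1.00,<0.001,0.99,0.99-1.00,0.08,1.00,0.99-1.01,0.64,0.98,0.97-0.99,<0.001
Na,100 mg/d,0.97,0.95-0.99,<0.01,1.00,0.97-1.03,0.76,0.97,0.94-1.00,0.09,0.90,0.86-0.95,<0.001
Mg,10 mg/d,0.95,0.93-0.97,<0.001,0.97,0.93-1.01,0.12,0.98,0.94-1.02,0.36,0.87,0.81-0.93,<0.001
Ca,100 mg/d,0.89,0.81-0.98,0.02,0.96,0.84-1.11,0.58,0.90,0.77-1.05,0.18,0.79,0.61-1.01,0.06
P,10 mg/d,0.98,0.97-0.99,<0.001,0.99,0.98-1.00,0.12,0.99,0.98-1.00,0.19,0.97,0.95-0.99,<0.01
Fe,mg/d,0.94,0.91-0.98,<0.01,0.97,0.91-1.04,0.41,0.98,0.93-1.03,0.36,0.77,0.69-0.87,<0.001
Zn,mg/d,0.86,0.80-0.93,<0.001,0.91,0.81-1.02,0.10,0.97,0.87-1.09,0.66,0.61,0.49-0.76,<0.001
Cu,mg/d,0.68,0.46-0.99,0.05,0.88,0.47-1.66,0.70,0.78,0.43-1.43,0.43,0.25,0.08-0.73,0.01
Mn,mg/d,0.80,0.70-0.92,<0.01,0.89,0.74-1.07,0.20,0.98,0.78-1.23,0.85,0.41,0.26-0.64,<0.001
Se,mg/d,1.00,0.98-1.01,0.61,1.02,0.99-1.04,0.22,0.99,0.96-1.01,0.24,0.99,0.95-1.03,0.63
Retinol,10 ug/d,1.01,0.99-1.02,0.36,1.02,1.01-1.03,<0.001,0.98,0.96-1.01,0.20,0.99,0.96-1.02,0.56
Vitamin A,100 ug RAE/d,0.98,0.92-1.05,0.60,1.09,1.00-1.18,0.04,1.01,0.91-1.12,0.85,0.72,0.60-0.88,<0.001
Carotene,100 ug/d,0.99,0.98-1.01,0.45,1.00,0.98-1.02,0.77,1.02,0.99-1.04,0.21,0.91,0.87-0.96,<0.001
Vitamin E,ug/d,0.97,0.95-1.00,0.04,1.01,0.98-1.05,0.48,0.97,0.93-1.01,0.14,0.93,0.87-0.99,0.02
Thiamine,mg/d,1.02,0.99-1.04,0.18,1.02,0.99-1.05,0.23,0.99,0.85-1.14,0.85,1.22,1.01-1.47,0.04
Riboflavin,mg/d,1.02,0.99-1.05,0.17,1.02,0.99-1.05,0.22,0.97,0.82-1.15,0.76,1.24,1.02-1.50,0.03
Nicotinic,mgNE/d,0.92,0.88-0.96,<0.001,0.93,0.87-0.99,0.03,0.99,0.93-1.06,0.80,0.75,0.67-0.85,<0.001
Ascorbic,mg/d,0.99,0.99-1.00,<0.01,1.00,0.99-1.00,0.15,1.00,1.00-1.01,0.21,0.97,0.96-0.98,<0.001
DPI,0.1 g/kg/d,0.85,0.79-0.92,<0.001,0.92,0.81-1.03,0.15,0.91,0.80-1.04,0.16,0.71,0.59-0.86,<0.001
DEI,kcal/kg/d,0.94,0.92-0.97,<0.001,0.97,0.92-1.01,0.13,0.96,0.92-1.01,0.10,0.87,0.81-0.94,<0.001
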