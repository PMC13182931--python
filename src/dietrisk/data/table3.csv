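variable,unit,recommended,mean_all,sd_all,p
Water,g/d,"No clear numerical value. For patients with stable fluid status, the daily fluid intake should be 500 ml plus the previous day's urine output and the previous day's net peritoneal dialysis ultrafiltration amount",1512.00,522.61,<0.01
Protein,g/d,see DPI,52.52,15.78,<0.001
Fat,g/d,25% to 35% of total calories,61.28,17.76,<0.01
Carbohydrate,g/d,The recommended carbohydrate energy contribution is between 55% and 65%,215.34,68.68,<0.001
Calories,kcal/d,see DEI,1582.30,450.26,<0.001
Df,g/d,19.8 g/d,10.18,3.75,<0.001
K,mg/d,"Normal 2,000 mg/d",1493.33,481.10,<0.001
Na,mg/d,"<2,300 mg/d",2595.51,925.01,0.13
Mg,mg/d,Normal 300-330 mg/d,253.39,80.37,<0.001
Ca,mg/d,"800-1,000 mg/d, <2,000 mg/d",437.14,168.42,0.12
P,mg/d,"800-1,000 mg/d",799.52,244.67,<0.01
Fe,mg/d,"Normal 10-18 mg/d, <42 mg/d",15.70,5.17,<0.001
Zn,mg/d,"Normal 8.5-12 mg/d, <40 mg/d",8.18,2.87,<0.01
Cu,mg/d,"Normal 0.7-0.8 mg/d, <8 mg/d",1.26,0.44,<0.001
Mn,mg/d,"Normal 4.0-4.5 mg/d, <11 mg/d",3.92,1.56,<0.001
Se,ug/d,"Normal 60 ug/d, <400 ug/d",35.71,11.36,<0.01
Retinol,ug/d,-,166.44,152.01,<0.01
Vitamin A,ug RAE/d,"normal 600-770 ug RAE/d, <30 ug RAE/d",469.28,272.27,0.73
Carotene,ug/d,-,1705.64,1228.01,<0.01
Vitamin E,ug/d,Normal <700 ug/d,21.99,9.31,<0.001
Thiamine,mg/d,Normal 1.2-1.4 mg/d,1.24,3.73,<0.01
Riboflavin,mg/d,Normal 1.2-1.4 mg/d,1.32,3.58,<0.01
Nicotinic,mgNE/d,Normal 12-15 mg NE/d,12.45,5.15,<0.001
Ascorbic,mg/d,"Male 90, female 75",88.43,48.69,<0.01
DPI,g/kg/d,1.0-1.2 g/kg/d,0.92,0.26,<0.01
DEI,kcal/kg/d,25-35 kcal/kg/d,27.60,7.37,<0.001
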