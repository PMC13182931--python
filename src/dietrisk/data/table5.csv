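nutrient,unit,a_all,b_all,c_all,p_all,pnl_all,a_low,b_low,c_low,p_low,pnl_low,a_medium,b_medium,c_medium,p_medium,pnl_medium,a_high,b_high,c_high,p_high,pnl_high
Water,100 g/d,14.11,-,-,<0.01,0.10,12.76,13.72,-,0.15,0.08,13.79,-,-,0.81,0.84,14.45,-,-,0.02,0.29
Protein,g/d,50.29,74.76,-,<0.001,<0.001,52.23,62.02,-,<0.01,<0.01,46.99,48.48,-,<0.01,0.01,51.29,-,-,<0.01,0.21
Fat,10 g/d,5.91,7.72,-,<0.001,<0.001,5.88,7.36,-,<0.001,<0.001,5.78,5.84,-,<0.001,<0.01,6.04,-,-,<0.001,0.49
Carbohydrate,g/d,206.26,382.04,-,<0.001,0.02,194.82,296.37,-,<0.01,<0.001,201.57,-,-,0.22,0.81,216.48,-,-,0.02,0.63
Calories,10 kcal/d,152.47,238.33,-,<0.001,<0.001,150.10,199.18,-,<0.001,<0.001,148.13,197.21,-,0.06,0.10,156.05,-,-,<0.001,0.42
Df,g/d,9.73,15.45,-,<0.001,<0.001,9.44,14.60,-,<0.001,<0.001,9.20,9.90,13.56,0.04,0.15,10.17,16.00,-,<0.001,<0.01
K,10 mg/d,144.09,235.32,-,<0.001,<0.001,142.06,213.51,-,0.03,0.05,133.14,138.99,-,0.04,0.02,148.89,-,-,<0.001,0.07
Na,100 mg/d,24.89,24.89,-,<0.001,<0.001,21.63,24.47,-,<0.001,<0.001,20.91,24.44,-,<0.001,<0.001,25.04,-,-,<0.001,0.87
Mg,10 mg/d,24.05,40.57,-,<0.001,<0.001,23.67,36.19,-,0.02,0.01,23.95,36.13,-,0.75,0.73,24.23,-,-,<0.001,0.02
Ca,100 mg/d,4.10,7.74,-,<0.001,0.01,4.20,-,-,0.81,0.85,3.94,4.07,-,<0.01,0.01,4.01,6.61,-,0.12,0.27
P,10 mg/d,76.06,117.12,-,<0.001,<0.001,77.96,98.67,-,<0.01,<0.01,73.77,101.97,-,0.28,0.33,77.26,-,-,<0.01,0.06
Fe,mg/d,14.81,26.70,-,<0.001,<0.001,14.27,20.09,-,<0.01,<0.001,14.37,24.64,-,0.59,0.56,15.34,-,-,<0.001,0.48
Zn,mg/d,7.58,12.27,-,<0.001,<0.001,7.39,11.05,-,<0.01,<0.01,7.57,8.49,-,0.21,0.11,7.61,-,-,<0.001,0.44
Cu,mg/d,1.18,2.28,-,0.04,0.21,1.14,1.14,-,0.13,0.06,1.12,1.14,1.38,0.93,0.97,1.28,-,-,0.03,0.49
Mn,mg/d,3.64,7.24,-,<0.001,<0.01,3.53,6.27,-,0.05,0.04,2.40,3.57,5.57,0.99,0.95,3.70,-,-,<0.001,0.63
Se,ug/d,34.60,37.70,-,<0.001,<0.001,34.44,38.76,-,<0.001,<0.001,29.75,33.09,-,0.09,0.10,36.24,53.34,-,0.21,0.11
Retinol,10 ug/d,14.06,14.59,-,<0.001,<0.001,9.19,15.95,-,<0.001,0.23,11.97,12.86,-,0.02,0.02,9.92,13.00,-,0.16,0.09
Vitamin A,100 ug RAE/d,4.17,7.18,-,<0.001,<0.001,4.20,6.65,-,<0.001,<0.001,4.05,4.22,-,0.04,0.02,3.45,4.17,6.26,<0.001,0.04
Carotene,100 ug/d,14.59,32.94,-,<0.001,<0.001,13.50,36.53,-,<0.001,<0.001,14.28,21.08,-,<0.01,<0.01,15.82,-,-,<0.01,0.60
Vitamin E,ug/d,20.47,33.62,-,<0.001,<0.001,20.19,22.67,-,<0.001,<0.001,20.19,28.31,-,0.19,0.21,21.40,-,-,0.06,0.93
Thiamine,mg/d,0.71,0.71,-,<0.001,<0.001,0.70,0.72,-,<0.01,<0.01,0.56,0.63,-,0.98,0.91,0.69,-,-,0.05,0.07
Riboflavin,mg/d,-,-,-,<0.001,<0.001,0.75,0.85,-,0.11,0.18,0.77,0.78,-,0.08,0.03,0.81,1.89,-,0.06,0.10
Nicotinic,mgNE/d,11.57,20.03,-,<0.001,<0.001,11.19,19.37,-,0.02,0.02,11.28,14.54,-,<0.01,<0.01,12.19,-,-,<0.001,0.18
Ascorbic,mg/d,79.27,-,-,<0.01,0.10,75.89,-,-,0.39,0.93,78.41,79.74,-,0.06,0.11,82.74,-,-,<0.001,0.04
DPI,0.1 g/kg/d,8.75,12.83,-,<0.001,<0.001,8.73,11.18,-,<0.01,<0.01,8.49,8.61,-,0.03,0.05,8.94,-,-,<0.01,0.68
DEI,kcal/kg/d,26.22,41.93,-,<0.001,<0.01,25.86,34.28,-,<0.01,<0.001,25.69,41.98,-,0.19,0.37,26.67,27.68,28.14,<0.01,0.13
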