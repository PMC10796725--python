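variety,gi_class,waxy,area_um2,area_sd,eccentricity,circularity,diameter_um,porosity_pct,porosity_sd,protein_g,protein_sd,ashes_g,ashes_sd,fat_g,fat_sd,amylose_pct,amylose_sd,gi_mean,gi_sd
Arborio,high,0,43.02,5.13,0.71,0.40,7.40,5.79,0.27,6.71,0.41,0.43,0.04,0.57,0.05,14.10,3.00,92.31,8.35
Lince,high,0,123.20,15.59,0.69,0.42,12.53,1.11,0.09,5.97,0.37,0.34,0.04,0.64,0.05,17.50,3.50,88.93,9.22
Duilio,high,0,34.90,6.50,0.73,0.37,6.67,4.12,3.05,7.78,0.48,0.60,0.05,0.78,0.06,9.60,2.30,86.22,10.18
Castelmochi,high,1,,,,,,0.89,0.23,7.54,0.46,0.66,0.05,1.44,0.09,< 5,,84.71,10.65
Padano,high,0,36.40,2.26,0.73,0.40,6.81,6.55,0.05,6.69,0.41,0.60,0.05,0.95,0.07,12.70,2.80,73.69,10.66
CL18,high,0,93.41,6.51,,,10.91,0.63,0.46,6.83,0.42,0.53,0.05,0.81,0.06,11.60,2.60,73.01,8.17
Puma,high,0,64.62,44.32,0.72,0.39,9.07,2.83,3.04,5.64,0.35,0.61,0.05,0.69,0.05,14.00,3.00,73.00,7.05
Baldo,high,0,74.90,24.86,0.72,0.40,9.77,3.60,2.91,7.28,0.45,0.48,0.04,0.78,0.06,14.20,3.00,71.42,6.44
CL 71,high,0,39.46,26.27,0.73,0.40,7.09,3.30,2.47,7.43,0.46,0.58,0.05,0.94,0.07,20.70,4.00,71.29,7.14
CL35,high,0,39.35,2.12,,,7.08,6.49,0.43,5.79,0.36,0.60,0.05,0.99,0.07,14.40,3.00,71.03,9.76
CL12,medium,0,42.55,8.74,,,7.36,3.48,4.50,6.78,0.42,0.54,0.05,0.94,0.07,13.00,2.80,68.69,7.03
S. Andrea,medium,0,38.06,6.42,0.73,0.39,6.96,5.95,0.28,5.93,0.37,0.51,0.05,0.74,0.06,15.20,3.10,66.49,7.64
Valente,medium,0,,,0.73,0.38,,0.69,0.59,7.18,0.44,1.08,0.07,0.75,0.06,12.10,2.70,66.17,6.86
Carnaroli,medium,0,36.85,6.54,0.70,0.40,6.85,5.89,0.27,6.63,0.41,0.40,0.04,0.75,0.06,20.70,4.00,64.17,6.50
CL388,medium,0,39.59,8.18,0.72,0.40,7.10,5.53,1.40,7.43,0.46,0.41,0.04,0.63,0.05,12.60,2.70,62.56,8.67
Tiberio,medium,0,52.58,37.36,0.73,0.42,8.18,3.07,2.24,6.66,0.41,0.58,0.05,0.91,0.06,23.90,4.50,61.77,5.99
CRLB1,medium,0,49.11,4.30,0.72,0.42,7.91,0.83,0.16,7.58,0.46,0.53,0.05,0.71,0.05,21.80,4.10,61.06,3.73
Elio,medium,0,44.48,5.99,0.72,0.39,7.53,6.42,0.44,5.98,0.37,0.41,0.04,0.76,0.06,22.90,4.30,60.39,5.87
Enr-18126,medium,0,68.57,27.12,0.72,0.38,9.35,3.40,2.93,7.34,0.45,0.22,0.04,0.70,0.05,17.70,3.50,58.45,5.83
Iarim,medium,0,55.43,30.14,0.74,0.38,8.40,3.83,2.30,7.36,0.45,0.59,0.05,0.92,0.06,24.40,4.50,58.00,9.29
Enr-18215,low,0,,,0.73,0.40,,0.77,0.25,6.69,0.41,0.46,0.04,0.88,0.06,12.00,2.70,54.26,6.79
Enr-18328,low,0,90.62,12.61,0.73,0.40,10.74,0.53,0.26,6.91,0.42,0.35,0.04,0.77,0.06,23.40,4.40,53.56,5.01
Argo,low,0,77.87,7.50,0.71,0.41,9.96,6.72,0.39,7.37,0.45,0.46,0.04,1.08,0.07,20.30,3.90,50.55,7.17
Enr-18433,low,0,,,0.72,0.40,,0.44,0.22,6.09,0.37,0.56,0.05,0.87,0.06,18.70,3.70,49.21,5.59
Selenio,low,0,107.77,24.93,0.71,0.43,,0.40,0.28,6.33,0.39,0.21,0.04,0.69,0.05,14.60,3.00,49.15,6.55
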