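variety,origin,waxy,area_um2,area_sd,eccentricity,circularity,diameter_um,porosity_pct,porosity_sd
CL31,italian,0,34.48,10.37,0.72,0.39,6.63,5.64,1.85
CL80,italian,0,,,0.73,0.38,,0.40,0.26
CL510,italian,0,50.55,0.65,0.74,0.39,8.03,5.30,0.71
Cripto,italian,0,33.24,2.15,,,6.51,6.15,0.59
CRW3,italian,1,35.61,18.79,0.68,0.40,6.74,6.35,0.54
Dedalo,italian,0,64.81,25.09,0.73,0.38,9.09,2.14,2.86
Drago,italian,0,75.02,32.28,0.71,0.39,9.78,6.35,0.20
Europa,italian,0,30.75,1.26,0.73,0.38,6.26,6.28,0.27
Italmochi,italian,1,,,0.68,0.41,,1.09,0.29
Pegaso,italian,0,69.83,38.27,0.71,0.41,9.43,1.33,1.41
Prometeo,italian,0,26.69,0.46,0.71,0.41,5.83,0.92,0.22
Kaluheenati,irri,0,29.39,4.86,0.74,0.37,6.12,5.66,1.52
Mahsuri,irri,0,28.22,7.01,,,6.00,5.74,1.10
Hetadawee,irri,0,53.45,13.04,,,8.25,6.52,0.67
Pajam,irri,0,26.70,0.72,0.73,0.40,5.83,5.97,0.24
Kahawanu,irri,0,,,0.72,0.36,,1.66,0.61
IR 42,irri,0,54.75,19.47,0.74,0.40,8.35,0.69,0.13
IR 6,irri,0,66.95,41.65,0.73,0.42,9.24,1.64,1.87
IR 50,irri,0,87.63,9.13,0.74,0.40,10.57,6.31,0.34
IR 64,irri,0,75.89,41.41,0.73,0.39,9.83,4.16,3.52
IR 4630-22-2-5-1-3,irri,0,21.04,11.69,0.72,0.40,5.18,5.18,0.55
Cisokan,irri,0,,,0.72,0.40,,0.52,0.01
Taichung Sen 17,irri,0,32.22,1.77,0.71,0.39,6.41,6.13,0.19
Doongara,irri,0,29.00,2.17,0.71,0.39,6.08,6.36,0.05
Sinandomeng,irri,0,,,,,,0.99,0.80
Iac 165,irri,0,52.87,29.26,0.74,0.39,8.21,4.27,3.14
Fedearroz 50,irri,0,89.17,1.99,0.72,0.42,10.66,0.79,0.39
Cypress,irri,0,84.12,7.16,0.71,0.39,10.35,0.89,0.21
Swarna,irri,0,49.62,29.61,,,7.95,4.75,3.37
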