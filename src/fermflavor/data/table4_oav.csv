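compound,threshold_ug_per_kg,HT1,HT2,HT3,HT4,HT5,HT6,HT7,HT8,HT9
Hexanal,7.5,4.48,409.86,459.84,671.5,345.3,181.33,115.49,337,111.62
Heptanal,10,0.69,34.21,32.95,47.18,22.47,18.8,24.78,33.1,9.27
Methional,0.04,-,-,-,-,-,-,525.33,807.55,334
Benzaldehyde,50,0.13,-,-,-,-,1.53,4.33,4.07,1.16
Octanal,0.1,148.04,5411.91,3805.37,6992.07,3188.86,3995.26,5535.58,5410.98,1268.06
Benzeneacetaldehyde,9,-,-,-,-,-,3.97,14.84,34.52,12.61
Nonanal,3.5,11.27,403.98,275.87,477.73,306.6,367.2,463.29,383.03,101.25
(E)-2-octenal,0.07,-,1577.11,3710.65,6882.78,2699.82,1707.69,1525.08,3295.86,780.82
Decanal,0.9,-,55.76,42.87,81.38,59.68,89.83,318.45,119.03,55.83
"(E,E)-2,4-Nonadienal",0.06,-,-,1200.57,1830.18,663.47,389.68,212.68,852.52,137
Undecanal,14,-,-,-,-,-,0.82,1.82,1.3,0.29
"(E,E)-2,4-Decadienal",0.03,-,-,1725.5,3698.97,1358.97,1208.43,1005.7,3887.7,379.63
Dodecanal,1.07,-,-,-,38.66,-,13.34,30.71,11.13,11.59
2-Heptanone,70,-,-,-,-,-,1,1.73,-,-
2-Nonanone,25,-,-,-,-,-,-,8.1,-,-
2-Undecanone,10,-,-,-,-,-,-,1.39,-,-
Hexanoic acid,200,-,0.21,1.48,2.63,1.34,0.37,0.05,0.24,0.11
1-Hexanol,200,-,0.24,0.16,0.32,0.13,1.06,0.7,0.34,0.37
1-Heptanol,200,-,0.57,0.54,0.95,0.42,0.61,0.62,0.66,-
1-Octen-3-ol,2,-,381.75,143.25,233.43,212.81,295.18,136.22,297.03,94.81
1-Octanol,54,-,3.52,-,-,-,4.24,-,-,-
Linalool,1.5,-,-,-,-,-,9.69,66.56,6.66,87.89
1-Nonanol,2,2.15,-,-,-,-,-,16.26,0,0
2-Pentyl-furan,4.8,-,17.74,16.51,25.73,19.21,17.03,42.63,36.78,21.26
2-Methoxy-phenol,0.17,-,-,-,-,-,-,-,-,124.76
Creosol,10,-,-,-,-,-,-,1.07,-,-
Estragole,7.5,-,7.99,6.39,-,-,-,18.67,3.54,12.32
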