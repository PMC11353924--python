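group,observed_otus_mean,observed_otus_sd,shannon_mean,shannon_sd,simpson_mean,simpson_sd,chao1_mean,chao1_sd,ace_mean,ace_sd,goods_coverage_mean,goods_coverage_sd
HT1,1198.00,74.67,4.61,1.96,0.83,0.18,1983.71,114.59,2048.28,136.15,0.99,0.00
HT2,1166.00,84.12,5.28,1.93,0.87,0.17,1896.46,77.46,2022.61,102.18,1.00,0.00
HT3,1400.00,78.48,4.78,0.93,0.86,0.09,2299.60,132.60,2369.53,102.40,0.99,0.00
HT4,1430.67,60.87,7.22,0.11,0.98,0.00,2339.85,80.57,2469.03,47.70,0.99,0.00
HT5,1264.67,128.59,5.27,0.49,0.90,0.05,2113.66,197.84,2322.46,170.39,0.99,0.00
HT6,1355.33,20.21,4.30,0.04,0.78,0.00,2115.79,49.11,2177.94,33.50,0.99,0.00
HT7,1404.00,277.70,6.35,0.50,0.95,0.02,2006.18,219.88,2125.99,235.03,0.99,0.00
HT8,1160.67,98.57,6.26,0.40,0.96,0.03,1924.93,127.87,2056.64,126.76,1.00,0.00
HT9,832.67,34.53,1.41,0.19,0.28,0.05,1293.89,20.65,1411.36,22.90,1.00,0.00
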