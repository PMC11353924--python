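group,observed_otus_mean,observed_otus_sd,shannon_mean,shannon_sd,simpson_mean,simpson_sd,chao1_mean,chao1_sd,ace_mean,ace_sd,goods_coverage_mean,goods_coverage_sd
HT1,290.00,117.48,2.84,1.48,0.71,0.17,418.71,206.38,409.47,209.09,1.00,0.00
HT2,371.00,116.50,3.87,1.86,0.82,0.21,608.01,179.59,562.92,196.29,1.00,0.00
HT3,453.67,35.50,3.56,0.58,0.80,0.05,681.33,81.51,701.86,77.60,1.00,0.00
HT4,517.00,44.31,4.28,0.34,0.87,0.04,736.83,39.29,780.05,41.75,1.00,0.00
HT5,416.00,25.12,3.49,0.22,0.81,0.02,637.21,27.76,671.17,42.81,1.00,0.00
HT6,443.67,6.43,2.29,0.03,0.67,0.01,687.36,40.14,666.42,20.26,1.00,0.00
HT7,335.33,38.03,0.57,0.02,0.11,0.01,534.35,23.44,526.25,60.44,1.00,0.00
HT8,493.67,37.42,2.92,0.34,0.69,0.07,726.49,31.17,741.44,51.36,1.00,0.00
HT9,266.00,31.43,1.22,0.20,0.38,0.11,378.32,44.55,387.73,55.90,1.00,0.00
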