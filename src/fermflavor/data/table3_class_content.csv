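compound,chem_class,HT1,HT2,HT3,HT4,HT5,HT6,HT7,HT8,HT9
Aldehydes,aldehyde,101.37,6224.53,7127.77,10527.94,5487.13,4693.04,4977.81,7101.65,2306.42
Ketones,ketone,-,76.26,148.58,127.63,149.612,190.8,523.12,375.31,170.57
Acids,acid,-,242.94,450.29,735.17,478.75,413.1,210.3,417.21,655.4
Esters,ester,20.64,555.53,178.68,381.4,1016.84,444.41,659.7,654.64,649.04
Alcohols,alcohol,25.88,1544.72,1699.12,2519.4,2142.66,1655.45,1038.01,1319.42,970.99
Hydrocarbons,hydrocarbon,-,696.99,659.16,1048.83,781.82,597.69,815.12,1012.76,611.6
Others,other,23.25,1373.82,1778.92,2015.28,927.68,1504.21,1138.2,981.63,515.97
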