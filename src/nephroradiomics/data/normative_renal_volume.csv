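age_lo_months,age_hi_months,upper_cm3,mean_cm3,lower_cm3
6,12,69.08,55.44,41.80
12,18,81.26,62.80,44.34
18,24,89.63,68.35,47.07
24,30,94.57,74.49,54.41
30,36,100.91,82.47,64.03
36,42,113.38,89.60,65.82
42,48,113.89,94.89,75.89
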