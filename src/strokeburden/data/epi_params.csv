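gender,band,prevalence_pct,risk_new_onset_per_100k,incident_cases,attack_rate_per_100k,first_year_survival_pct,nonstroke_mortality_per_100k
male,45,0.68,176,6963,214,82.76,417
male,55,1.95,444,11615,577,70.42,837
male,65,4.15,1090,16493,1447,65.01,2128
male,75,6.27,2022,10043,2777,45.27,5265
male,85,6.96,2840,2160,3845,34.31,17923
female,45,0.47,113,4288,135,82.90,144
female,55,1.56,287,8100,376,83.36,283
female,65,3.42,758,16485,1053,69.66,823
female,75,5.16,1570,16639,2314,49.57,2982
female,85,4.86,2471,5362,3118,26.35,14217
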