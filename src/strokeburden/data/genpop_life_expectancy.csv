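gender,age,life_expectancy_years
male,45,32.16
male,55,23.6
male,65,15.8
male,75,9.42
male,85,5.16
female,45,38.28
female,55,28.9
female,65,19.9
female,75,11.91
female,85,6.28
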