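gender,band,cost_first_year,cost_subsequent_year,cost_fatal,cost_premature_death
male,45,8449,1250,10543,521179
male,55,7324,1564,11366,141230
male,65,5134,1530,8724,0
male,75,4772,1946,7490,0
male,85,5075,1804,6143,0
female,45,5358,629,12182,171802
female,55,5032,1004,9955,54111
female,65,4891,1309,11135,0
female,75,4915,1656,7993,0
female,85,4669,1588,5514,0
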