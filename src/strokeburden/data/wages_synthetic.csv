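# Synthetic gender x age-band annual wage schedule (thousand KRW/year).
# The national wage statistics behind the published premature-death costs are
# not reproduced here; this file is a plausible stand-in for testing the
# productivity-cost assembly rules and is labelled synthetic for that reason.
gender,band,annual_wage
male,45,30000
male,55,28000
male,65,0
male,75,0
male,85,0
female,45,17000
female,55,15000
female,65,0
female,75,0
female,85,0
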