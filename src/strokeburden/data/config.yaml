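# Base-case model configuration (2008 KRW; money in thousand KRW).
cycle_length_years: 1.0
terminal_age: 99
retirement_age: 65
smr_male: 1.914
smr_female: 2.295
productivity_mode: human_capital
friction_period_years: 0.5
training_cost_usd_2000: 362.0
cpi_2008_base_2000: 129.3
exchange_rate_krw_per_usd: 1200.0
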