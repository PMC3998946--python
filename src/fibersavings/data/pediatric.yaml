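schema_version: 1
reporting_year: 2012
population_scope: pediatric
dose_response:
  per_gram_reduction: 0.019
shift:
  9.0: 1.0
strata:
- label: adult_male
  age_group: adult
  population_count: 116400000.0
  pct_meeting_recs: 0.03
  constipation_prev: 0.046
  responder_frac: 0.85
  rx_frac: 0.75
  rx_annual_cost: 10786.15
  otc_annual_cost: 566.54
- label: adult_female
  age_group: adult
  population_count: 123600000.0
  pct_meeting_recs: 0.06
  constipation_prev: 0.046
  responder_frac: 0.85
  rx_frac: 0.75
  rx_annual_cost: 10786.15
  otc_annual_cost: 566.54
- label: pediatric_male
  age_group: pediatric
  population_count: 27000000.0
  pct_meeting_recs: 0.03
  constipation_prev: 0.046
  responder_frac: 0.85
  rx_frac: 1.0
  rx_annual_cost: 3032.97
  otc_annual_cost: 566.54
  shift:
    6.0: 1.0
- label: pediatric_female
  age_group: pediatric
  population_count: 27000000.0
  pct_meeting_recs: 0.03
  constipation_prev: 0.046
  responder_frac: 0.85
  rx_frac: 1.0
  rx_annual_cost: 3032.97
  otc_annual_cost: 566.54
  shift:
    6.0: 1.0
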