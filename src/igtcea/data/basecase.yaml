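# Base-case inputs for the two-year SMS diabetes-prevention programme in
# subjects with impaired glucose tolerance.  Costs are 2011 US$ (Hong Kong
# dollars pegged at HKD 7.8 per US$).  Incidences are events per
# person-year; all probabilities refer to one annual cycle.

# Intervention effect (trial NCT01556880, complete-case analysis)
rr_t2dm_year1: 0.34
rr_t2dm_year2: 0.60
dropout_year1: 0.3889
dropout_year2: 0.3030

# Natural history of dysglycaemia
incidence_igt_to_t2dm_y1_3: 0.110   # 11.0 cases per 100 person-years, years 1-3
incidence_igt_to_t2dm_y4plus: 0.056 # 5.6 per 100 person-years, year 4 onwards
p_igt_to_ngt: 0.1620
p_ngt_to_igt: 0.1630
rr_mortality_igt: 1.5
rr_mortality_t2dm: 2.3

# Health-state utilities
utility_ngt: 0.76
utility_igt: 0.76
utility_t2dm: 0.72
utility_dead: 0.0

# Unit costs.  SMS programme costs per retained subject-year, split into
# message delivery and staff time; annual totals are summed from these
# components.  The T2DM cost is the annual medical cost per prevalent case.
cost_components:
  delivery_year1: 4.15
  staff_year1: 30.23
  delivery_year2: 0.92
  staff_year2: 6.72
cost_t2dm_annual: 1727.90

# Analysis settings
discount_rate: 0.03
horizon_years: 50
start_age: 55

# Optional direct overrides of the SMS-arm annual onset probability in
# intervention years (null = derive as rr * control probability)
p_igt_to_t2dm_sms_y1: null
p_igt_to_t2dm_sms_y2: null

# Which retained states incur programme cost: all_retained | igt_only
intervention_cost_states: all_retained

# One-way sensitivity ranges (min, max); keys are sweepable names
sensitivity_ranges:
  dropout_year1: [0.0, 1.0]
  dropout_year2: [0.0, 1.0]
  incidence_igt_to_t2dm_y1_3: [0.098, 0.123]
  incidence_igt_to_t2dm_y4plus: [0.048, 0.065]
  rr_t2dm_year1: [0.10, 1.00]
  rr_t2dm_year2: [0.10, 1.00]
  p_igt_to_t2dm_sms_y1: [0.0093, 0.1157]
  p_igt_to_t2dm_sms_y2: [0.0093, 0.1157]
  p_igt_to_ngt: [0.05, 0.25]
  p_ngt_to_igt: [0.05, 0.25]
  rr_mortality_igt: [1.1, 2.0]
  rr_mortality_t2dm: [1.6, 3.2]
  discount_rate: [0.0, 0.05]
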