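# Bundled one-way sensitivity scenarios: each varies one (or one group of)
# model input(s) from the base case.  Paths are dotted config paths.
- name: base_case
  overrides: {}
- name: relapse_time_halved
  overrides: {natural_history.mean_time_relapse: 0.68}
- name: relapse_time_doubled
  overrides: {natural_history.mean_time_relapse: 2.718}
- name: complication_to_depression_hr_1.0
  overrides: {natural_history.hr_complication_on_depression: 1.0}
- name: complication_to_depression_hr_2.0
  overrides: {natural_history.hr_complication_on_depression: 2.0}
- name: depression_to_complication_hrs_null
  overrides:
    complications.hr_micro_minor: 1.0
    complications.hr_micro_major: 1.0
    complications.hr_macro_minor: 1.0
    complications.hr_macro_major: 1.0
- name: major_depression_disutility_-0.2
  overrides: {utilities.decrements.major_depression: -0.2}
- name: major_depression_disutility_-0.4
  overrides: {utilities.decrements.major_depression: -0.4}
- name: screen_cost_0
  overrides: {costs.opportunistic_screen: 0.0}
- name: screen_cost_4
  overrides: {costs.opportunistic_screen: 4.0}
- name: collaborative_care_cost_halved
  overrides: {treatment.cc_addon_cost: 120.0}
- name: collaborative_care_cost_doubled
  overrides: {treatment.cc_addon_cost: 480.0}
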