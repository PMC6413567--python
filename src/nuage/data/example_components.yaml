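# ILLUSTRATIVE 16-component scoring spec for the 0-160 adherence index.
#
# The component list mirrors a Mediterranean-style food-based dietary
# guideline set: eleven adequacy components (more is better), two range
# components with minimum and maximum intake frequencies (whole grains,
# eggs), and three components to limit (alcohol, sodium, sweets).
# The numeric cutoffs below are EXAMPLES chosen on plausible scales
# (g/day, servings/week, liters/day ...); real analyses must supply the
# guideline set's own cutoffs via a file like this one.
#
# cap_rule entries replace the capping cutoff with a per-country
# empirical percentile of observed intake (e.g. 85th percentile for
# sodium and sweets, 100th for whole grains and low-fat meat).
components:
  - {name: whole_grains, kind: range, zero_score_cutoff: 0.0, full_score_cutoff: 90.0,
     full_score_cutoff_high: 200.0, zero_score_cutoff_high: 400.0,
     cap_rule: {percentile: 100, per_country: true}}
  - {name: fruits, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 200.0}
  - {name: vegetables, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 250.0}
  - {name: legumes, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 25.0}
  - {name: low_fat_dairy, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 150.0}
  - {name: low_fat_cheese, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 25.0}
  - {name: fish, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 35.0}
  - {name: low_fat_meat, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 70.0,
     cap_rule: {percentile: 100, per_country: true}}
  - {name: nuts, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 15.0}
  - {name: olive_oil, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 20.0}
  - {name: fluids, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 1.5}
  - {name: vitamin_d_supplement, kind: adequacy, zero_score_cutoff: 0.0, full_score_cutoff: 10.0}
  - {name: eggs, kind: range, zero_score_cutoff: 0.0, full_score_cutoff: 2.0,
     full_score_cutoff_high: 4.0, zero_score_cutoff_high: 7.0}
  - {name: alcohol, kind: limit, full_score_cutoff: 10.0, zero_score_cutoff: 30.0}
  - {name: sodium, kind: limit, full_score_cutoff: 1500.0, zero_score_cutoff: 2400.0,
     cap_rule: {percentile: 85, per_country: true}}
  - {name: sweets, kind: limit, full_score_cutoff: 25.0, zero_score_cutoff: 75.0,
     cap_rule: {percentile: 85, per_country: true}}
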