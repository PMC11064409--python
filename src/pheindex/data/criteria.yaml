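# Versioned default criterion configuration: tiers, scores and thresholds
# for the 13 phenotyping criteria.  Threshold maps keyed by term status
# where the rule is term-specific.
version: 1
criteria:
  nicu_stay:
    tier: major
    score: 3
    thresholds: {admit_window_days: 7, min_stay_days: 4}
  hospitalizations:
    tier: major
    score: 3
    thresholds:
      min_episode_hours: 48
      prolonged_days: 14
      pma_floor_days: 245
      min_count: {full_term: 2, pre_term: 3}
  multiple_specialists:
    tier: minor
    score: 1
    thresholds:
      min_types: {full_term: 3, pre_term: 4}
  er_visits:
    tier: minor
    score: 1
    thresholds:
      min_visits: {full_term: 5, pre_term: 7}
  feeding_support:
    tier: minor
    score: 2
    thresholds: {}
  respiratory_support:
    tier: minor
    score: 2
    thresholds: {days_before: 1, days_after: 5}
  imaging:
    tier: minor
    score: 1
    thresholds: {}
  genetic_tests:
    tier: minor
    score: 1
    thresholds: {}
  metabolic_tests:
    tier: minor
    score: 1
    thresholds: {}
  death:
    tier: major
    score: 3
    thresholds: {}
  developmental_delay:
    tier: minor
    score: 1
    thresholds: {min_icd_dates: 2}
  metabolic_icd:
    tier: major
    score: 3
    thresholds: {min_encounters: 2}
  heart_surgery:
    tier: major
    score: 3
    thresholds: {}
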