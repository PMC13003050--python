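# Default 3x3 NO2 risk-matrix profile.
#
# Likelihood (L): fraction of the work shift spent at the location.
# Severity (S): indoor NO2 concentration band (ug/m3) and its health effects.
# Outer bands are strict (< 25%, > 75%; < 500, > 2000), so each middle band
# is closed on both ends and the bands partition the domain.
likelihood_bands:
  - score: 1
    lower: 0.0
    upper: 0.25
    lower_inclusive: true
    upper_inclusive: false
    description: Unlikely
  - score: 2
    lower: 0.25
    upper: 0.75
    lower_inclusive: true
    upper_inclusive: true
    description: likely
  - score: 3
    lower: 0.75
    upper: 1.0
    lower_inclusive: false
    upper_inclusive: true
    description: Very likely

severity_bands:
  - score: 1
    lower: 0.0
    upper: 500.0
    lower_inclusive: true
    upper_inclusive: false
    description: Minor effect
  - score: 2
    lower: 500.0
    upper: 2000.0
    lower_inclusive: true
    upper_inclusive: true
    description: Moderate effect
  - score: 3
    lower: 2000.0
    upper: .inf
    lower_inclusive: false
    upper_inclusive: false
    description: Major effect

# RF = L x S -> category; colours are green / yellow / bright_red / deep_red.
category_map:
  1: low
  2: low
  3: moderate
  4: moderate
  6: high
  9: very_high
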