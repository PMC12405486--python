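# Bundled parameter set: zanzibar drug-price scenario.
drug_prices:
  methotrexate:
    value: 45
    low: 22.5
    high: 67.5
  sulfasalazine:
    value: 127
    low: 63.5
    high: 190.5
  hydroxychloroquine:
    value: 111
    low: 55.5
    high: 166.5
  btsdmard1:
    value: 94
    low: 47.0
    high: 141.0
  btsdmard2:
    value: 5456
    low: 2728.0
    high: 8184.0
  prednisolone:
    value: 20
    low: 10.0
    high: 30.0
  rescue_supplement:
    value: 0.0
    low: 0.0
    high: 0.0
drugs:
  methotrexate:
    price_components:
    - methotrexate
    is_biologic: false
    profile:
      remission:
        value: 0.09
        low: 0.0675
        high: 0.1125
      lda:
        value: 0.34
        low: 0.255
        high: 0.425
      mda:
        value: 0.38
        low: 0.285
        high: 0.475
      hda:
        value: 0.19
        low: 0.1425
        high: 0.2375
  triple_therapy:
    price_components:
    - methotrexate
    - sulfasalazine
    - hydroxychloroquine
    is_biologic: false
    profile:
      remission:
        value: 0.1
        low: 0.075
        high: 0.125
      lda:
        value: 0.41
        low: 0.3075
        high: 0.5125
      mda:
        value: 0.33
        low: 0.2475
        high: 0.4125
      hda:
        value: 0.16
        low: 0.12
        high: 0.2
  btsdmard1:
    price_components:
    - btsdmard1
    is_biologic: true
    profile_early:
      remission:
        value: 0.12
        low: 0.09
        high: 0.15
      lda:
        value: 0.46
        low: 0.345
        high: 0.575
      mda:
        value: 0.28
        low: 0.21
        high: 0.35
      hda:
        value: 0.14
        low: 0.105
        high: 0.175
    profile_late:
      remission:
        value: 0.11
        low: 0.0825
        high: 0.1375
      lda:
        value: 0.41
        low: 0.3075
        high: 0.5125
      mda:
        value: 0.32
        low: 0.24
        high: 0.4
      hda:
        value: 0.16
        low: 0.12
        high: 0.2
  btsdmard2:
    price_components:
    - btsdmard2
    is_biologic: true
    profile_early:
      remission:
        value: 0.12
        low: 0.09
        high: 0.15
      lda:
        value: 0.3
        low: 0.225
        high: 0.375
      mda:
        value: 0.39
        low: 0.2925
        high: 0.4875
      hda:
        value: 0.19
        low: 0.1425
        high: 0.2375
    profile_late:
      remission:
        value: 0.12
        low: 0.09
        high: 0.15
      lda:
        value: 0.25
        low: 0.1875
        high: 0.3125
      mda:
        value: 0.42
        low: 0.315
        high: 0.525
      hda:
        value: 0.21
        low: 0.1575
        high: 0.2625
rescue:
  price_components:
  - methotrexate
  - prednisolone
  - rescue_supplement
  p_reach_target_per_cycle:
    value: 0.43
    low: 0.3225
    high: 0.5375
strategies:
- id: 1
  label: Methotrexate
  lines:
  - drug: methotrexate
    profile: early
- id: 2
  label: Methotrexate then triple therapy
  lines:
  - drug: methotrexate
    profile: early
  - drug: triple_therapy
    profile: early
- id: 3
  label: Methotrexate then b/tsDMARD1
  lines:
  - drug: methotrexate
    profile: early
  - drug: btsdmard1
    profile: early
- id: 4
  label: Methotrexate then triple therapy then b/tsDMARD1
  lines:
  - drug: methotrexate
    profile: early
  - drug: triple_therapy
    profile: early
  - drug: btsdmard1
    profile: late
- id: 5
  label: Methotrexate then triple therapy then two b/tsDMARDs
  lines:
  - drug: methotrexate
    profile: early
  - drug: triple_therapy
    profile: early
  - drug: btsdmard1
    profile: late
  - drug: btsdmard2
    profile: late
- id: 6
  label: Methotrexate then two consecutive b/tsDMARDs
  lines:
  - drug: methotrexate
    profile: early
  - drug: btsdmard1
    profile: early
  - drug: btsdmard2
    profile: early
costs:
  diagnosis:
    value: 125
    low: 62.5
    high: 187.5
  bridging:
    value: 6
    low: 3.0
    high: 9.0
  cs_first_cycle_investigations:
    value: 57
    low: 28.5
    high: 85.5
  cs_continuation:
    value: 25
    low: 12.5
    high: 37.5
  bts_startup_investigations:
    value: 157
    low: 78.5
    high: 235.5
  bts_continuation:
    value: 7
    low: 3.5
    high: 10.5
  clinic_visit:
    value: 4
    low: 2.0
    high: 6.0
  visits_first_cycle: 4
  visits_at_target: 1
  visits_off_target: 2
utilities:
  remission:
    value: 0.87
    low: 0.6525
    high: 1.0875
  lda:
    value: 0.72
    low: 0.54
    high: 0.9
  mda:
    value: 0.57
    low: 0.4275
    high: 0.7125
  hda:
    value: 0.21
    low: 0.1575
    high: 0.2625
  target:
    value: 0.77
    low: 0.5775
    high: 0.9625
  nontarget:
    value: 0.45
    low: 0.3375
    high: 0.5625
  use_pooled_target_utilities: false
mortality:
  baseline_annual_mortality:
    value: 0.004
    low: 0.003
    high: 0.005
  smr:
    remission: 1.0
    lda: 1.29
    mda: 1.42
    hda: 1.42
rules:
  p_stay_target:
    value: 0.8
    low: 0.6
    high: 1.0
  target_split:
  - 1
  - 2
  nontarget_split:
  - 2
  - 1
  rescue_mode: one_shot
  rescue_at_relapse: false
economics:
  cycle_length_years: 0.5
  horizon_years: 3.0
  annual_discount_rate: 0.03
  wtp_thresholds:
  - 282.0
  - 1136.0
  - 2272.0
  half_cycle_correction: true
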