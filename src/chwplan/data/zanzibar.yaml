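# Zanzibar community health volunteer (CHV) program: 2018 population
# statistics and the workforce/time-policy parameters adopted in the
# national community health strategy.  The 52-week year is a fixture
# parameter (the program states the weekly commitment, not the working
# year); travel absorbs one third of available time.
name: zanzibar
profile:
  name: Zanzibar
  total_population: 1579849
  group_counts:
    under-5: 268574
cadres:
  - name: CHV
    headcount: 2200
    time_policy:
      hours_per_week: 18
      weeks_per_year: 52
      travel_share: 0.3333333333333333
known_values:
  chvs:
    value: 2200
    note: adopted CHV workforce size
  persons-per-chv:
    value: 720
    note: reported catchment, approximately 720 persons per CHV (nearest ten)
  households-per-chv:
    value: 135
    note: reported catchment, households per CHV
  hours-per-week:
    value: 18
    note: maximum weekly time commitment, travel included
  travel-share:
    value: 0.3333333333333333
    note: travel reported to occupy one third of available time
  target-coverage:
    value: 0.9
    note: coverage goal of the adopted service package
  under-5-population:
    value: 268574
    note: reported under-5 count (2018 statistics)
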