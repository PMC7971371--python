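# Rwanda, rural Eastern typology (higher malaria incidence).
# Population figures are 2012-census based; cadre headcounts are the
# regional allocation of the three national CHW cadres.  Time policies
# for the Rwandan cadres were not published, so cadres carry headcounts
# only; the per-HP-CHW demand/supply aggregates are recorded as known
# values instead.
name: rwanda-eastern
profile:
  name: Rwanda Rural Eastern
  total_population: 2600814
  group_counts:
    under-5: 338106
cadres:
  - name: ASM
    headcount: 3794
  - name: binome
    headcount: 7799
  - name: HP-CHW
    headcount: 3837
known_values:
  population-per-chw:
    value: 169
    note: reported persons per CHW across all cadres (regional typology table)
  under-5-population:
    value: 338106
    note: reported under-5 count (regional typology table)
  hp-chw-annual-demand-hours:
    value: 1300
    note: >-
      reported aggregate: annual hours of assigned work per
      health-promotion CHW under the default scope of work ("in excess
      of 1,300 hours")
  hp-chw-available-hours:
    value: 632
    note: >-
      reported aggregate: annual hours available per health-promotion
      CHW; the inputs behind this figure were not published, so it is
      carried as a given constant
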