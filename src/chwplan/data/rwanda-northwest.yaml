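# Rwanda, rural Northern and Western typology (lower malaria incidence).
# Population figures are 2012-census based; cadre headcounts are the
# regional allocation of the three national CHW cadres.
name: rwanda-northwest
profile:
  name: Rwanda Rural Northern and Western
  total_population: 2178695
  group_counts:
    under-5: 286259
cadres:
  - name: ASM
    headcount: 3456
  - name: binome
    headcount: 6949
  - name: HP-CHW
    headcount: 3392
known_values:
  population-per-chw:
    value: 158
    note: reported persons per CHW across all cadres (regional typology table)
  under-5-population:
    value: 286259
    note: reported under-5 count (regional typology table)
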