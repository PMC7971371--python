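# Rwanda national program: 2019 workforce totals for the three cadres
# and the 2019 national population estimate (12.37 million).
name: rwanda-national
profile:
  name: Rwanda
  total_population: 12370000
cadres:
  - name: ASM
    headcount: 15361
  - name: binome
    headcount: 29314
  - name: HP-CHW
    headcount: 13892
known_values:
  total-chws:
    value: 58567
    note: reported national CHW workforce (sum of the three cadres)
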