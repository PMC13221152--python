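# Default ICD-10 code sets and ATC prefix groups.
#
# Three-character entries match any subcode of that category (N92 matches
# N92.0); longer entries match exactly. Ranges are inclusive over the
# three-character category ordering, with optional excluded sub-ranges.
# Every set can be overridden from a user-supplied file of the same shape.
code_sets:
  pregnancy:
    ranges: [["O00", "O99"]]
    exclude_ranges: [["O85", "O92"]]   # puerperium complications never censor
  abortion:
    codes: [O04]
  initiation_reasons:
    codes: [Z30, N92, O04, N94, L70, E28.2]
  side_effect_panel:
    # excessive/frequent menstruation, migraine, other headache, acne,
    # menstrual pain, depressive episode, anxiety, mastodynia
    codes: [N92, G43, R51, L70, N94, F32, F41, N64.4]
  vte_ate:
    codes: [I80, I80.2, I80.3, I26.9, I82.8]
  hypertension:
    ranges: [["I10", "I15"]]
  hyperlipidaemia:
    codes: [E78]
  diabetes:
    ranges: [["E10", "E14"]]
  pneumonia:
    ranges: [["J12", "J18"]]
  cardiovascular_disease:
    ranges: [["I20", "I25"]]
  cancer:
    ranges: [["C00", "C97"]]
  smoking_related:
    codes: [F17]
  other_thrombosis_risk:
    codes: [D68, I83]
atc_prefixes:
  hc_level3: [G02B, G03A]
  hc_exact: [G03HB01]
  emergency_contraceptive: [G03AD]
  risk_medications: [H02, N05A, N06A]
  antithrombotics: [B01A]
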