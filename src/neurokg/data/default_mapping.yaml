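# Default field-mapping configuration for the two bundled source dialects.
# Each entry harmonizes one (source, header) pair onto a registered pattern
# key. The per-source extra instrument columns (RBANS_total, HVLTRT) are
# deliberately left unmapped: they surface in the harmonization report.
mappings:
  # dataset1: verbose export dialect
  - {source: dataset1, header: GROUP, pattern_key: group_label, type: text}
  - {source: dataset1, header: SEX, pattern_key: sex, type: text}
  - {source: dataset1, header: AGE, pattern_key: age_years, type: decimal, range: [0, 120]}
  - {source: dataset1, header: EDUC_Years, pattern_key: education_years, type: decimal, range: [0, 30]}
  - {source: dataset1, header: HY_stage, pattern_key: hoehn_yahr, type: decimal, range: [0, 5]}
  - {source: dataset1, header: MOCA_total, pattern_key: moca_total, type: integer, range: [0, 30]}
  - {source: dataset1, header: MOCA_words_total, pattern_key: moca_category_fluency, type: integer, range: [0, 60]}
  - {source: dataset1, header: L_HIPPO_VOL, pattern_key: volume_left_hippocampus, type: decimal}
  - {source: dataset1, header: R_HIPPO_VOL, pattern_key: volume_right_hippocampus, type: decimal}
  - {source: dataset1, header: ICV_total, pattern_key: icv, type: decimal}
  # dataset2: terse export dialect (coded group and sex values)
  - {source: dataset2, header: APPRDX, pattern_key: group_label, type: text, value_map: {"1": PD, "2": HC}}
  - {source: dataset2, header: GENDER, pattern_key: sex, type: text, value_map: {"0": F, "1": M}}
  - {source: dataset2, header: AGEONVIS, pattern_key: age_years, type: decimal, range: [0, 120]}
  - {source: dataset2, header: EDUCYRS, pattern_key: education_years, type: decimal, range: [0, 30]}
  - {source: dataset2, header: NHY, pattern_key: hoehn_yahr, type: decimal, range: [0, 5]}
  - {source: dataset2, header: MCATOT, pattern_key: moca_total, type: integer, range: [0, 30]}
  - {source: dataset2, header: MCAVF, pattern_key: moca_category_fluency, type: integer, range: [0, 60]}
  - {source: dataset2, header: LHIPVOL, pattern_key: volume_left_hippocampus, type: decimal}
  - {source: dataset2, header: RHIPVOL, pattern_key: volume_right_hippocampus, type: decimal}
  - {source: dataset2, header: EICV, pattern_key: icv, type: decimal}
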