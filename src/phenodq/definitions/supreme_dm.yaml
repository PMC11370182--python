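# SUPREME-DM registry definition: two qualifying markers, where medication
# evidence alone never suffices — diagnoses on two distinct days within two
# years, two elevated HbA1c results, or a medication paired with a diagnosis
# or an elevated laboratory result.
name: SUPREME_DM
pathways:
  - name: two_dx_within_2y
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 2, distinct_days: true,
         window_days: 730}
  - name: two_elevated_hba1c
    criteria:
      - {data_type: LAB, code_set: hba1c, min_count: 2, distinct_days: true,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
  - name: dx_plus_rx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1}
      - {data_type: RX, code_set: t2d_rx, min_count: 1}
  - name: dx_plus_lab
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1}
      - {data_type: LAB, code_set: hba1c, min_count: 1,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
  - name: rx_plus_lab
    criteria:
      - {data_type: RX, code_set: t2d_rx, min_count: 1}
      - {data_type: LAB, code_set: hba1c, min_count: 1,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
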