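# eMERGE network T2D case algorithm (structured-data arm): no pathway admits
# a patient on diagnosis alone, medication alone, or medication plus
# laboratory alone — diagnosis evidence must be corroborated, and laboratory
# evidence stands alone only when repeated.
name: EMERGE
pathways:
  - name: two_elevated_hba1c
    criteria:
      - {data_type: LAB, code_set: hba1c, min_count: 2, distinct_days: true,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
  - name: dx_plus_rx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1}
      - {data_type: RX, code_set: t2d_rx, min_count: 1}
  - name: two_dx_plus_lab
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 2, distinct_days: true}
      - {data_type: LAB, code_set: hba1c, min_count: 1,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
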