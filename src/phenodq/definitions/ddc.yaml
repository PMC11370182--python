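# Durham Diabetes Coalition surveillance definition: the most permissive
# pathway set — diagnosis, medication, or elevated laboratory evidence each
# identify a patient on their own.
name: DDC
pathways:
  - name: two_dx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 2, distinct_days: true}
  - name: inpatient_dx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1, setting: inpatient}
  - name: any_rx
    criteria:
      - {data_type: RX, code_set: t2d_rx, min_count: 1}
  - name: elevated_hba1c
    criteria:
      - {data_type: LAB, code_set: hba1c, min_count: 1,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
  - name: elevated_random_glucose
    criteria:
      - {data_type: LAB, code_set: glucose_random, min_count: 1,
         predicate: {op: ge, threshold: 200, unit: "mg/dL"}}
  - name: elevated_fasting_glucose
    criteria:
      - {data_type: LAB, code_set: glucose_fasting, min_count: 1,
         predicate: {op: ge, threshold: 126, unit: "mg/dL"}}
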