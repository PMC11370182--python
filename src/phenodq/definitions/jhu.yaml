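# Johns Hopkins expert definition: no pathways in the published sense — any
# single data type suffices (one T2D diagnosis, one antidiabetic dispensing,
# or one elevated HbA1c), making it structurally the most inclusive.
name: JHU
pathways:
  - name: any_dx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1}
  - name: any_rx
    criteria:
      - {data_type: RX, code_set: t2d_rx, min_count: 1}
  - name: elevated_hba1c
    criteria:
      - {data_type: LAB, code_set: hba1c, min_count: 1,
         predicate: {op: ge, threshold: 6.5, unit: "%"}}
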