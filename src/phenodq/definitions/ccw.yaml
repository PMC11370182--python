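# CMS Chronic Conditions Warehouse diabetes flag: diagnosis codes only,
# counted within a trailing 2-year reference period — one inpatient claim or
# two outpatient claims on distinct days.
name: CCW
reference_period_days: 730
pathways:
  - name: inpatient_dx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 1, setting: inpatient}
  - name: two_outpatient_dx
    criteria:
      - {data_type: DX, code_set: t2d_dx, min_count: 2, distinct_days: true}
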