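# Shared code sets referenced by the shipped phenotype definitions.
# ICD-10 diagnosis sets match by prefix on dot-stripped codes (the family
# code E11 matches any E11.x child); RxNorm and LOINC sets match exactly.
t2d_dx:
  code_system: ICD10
  match_mode: prefix
  codes: [E11]

# Diabetes-adjacent diagnosis families kept distinct from the qualifying set;
# used as a curated replacement pool for the code-inaccuracy operator.
t2d_dx_pool:
  code_system: ICD10
  match_mode: prefix
  codes: [E08, E09, E10, E11, E13, O24]

# Ingredient-level RxNorm concepts for antidiabetic drug classes:
# metformin, sulfonylureas, DPP-4 / SGLT2 / GLP-1 agents, insulins.
t2d_rx:
  code_system: RXNORM
  match_mode: exact
  codes: ["6809", "4821", "4815", "25789", "593411", "857974", "1100699",
          "1373458", "1488564", "1545653", "60548", "475968", "1551291",
          "1991302", "5856", "274783", "139825", "86009"]

hba1c:
  code_system: LOINC
  match_mode: exact
  codes: ["55454-3", "4548-4"]

glucose_random:
  code_system: LOINC
  match_mode: exact
  codes: ["2345-7"]

glucose_fasting:
  code_system: LOINC
  match_mode: exact
  codes: ["1558-6"]
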