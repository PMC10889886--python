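# Parallel antibody capture on 1 mL Protein A columns: 10 CV equilibration,
# 10 CV load, 30 CV wash, low-pH elution as five 0.85 CV fractions into
# tubes pre-loaded by the operator with 0.15 CV of 1 M Tris pH 9.0.
name: protein_a_1ml
description: Protein A antibody purification, 1 mL column variant.
steps:
  - kind: equilibrate
    buffer_port: 1
    volume_cv: 10
  - kind: load
    volume_cv: 10
    collect_flowthrough: true
  - kind: wash
    buffer_port: 1
    volume_cv: 30
  - kind: elute
    buffer_port: 2
    volume_cv: 4.25
    fraction_size_cv: 0.85
    prefill_cv: 0.15
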