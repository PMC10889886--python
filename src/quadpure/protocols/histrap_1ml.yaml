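# Parallel IMAC purification on 1 mL columns: 10 CV equilibration,
# 50 CV load (flow-through captured in 50 mL tubes), 60 CV wash,
# elution collected as eight 1 CV fractions.  All steps at 1 CV/min.
name: histrap_1ml
description: His-tag IMAC purification, 1 mL column variant.
steps:
  - kind: equilibrate
    buffer_port: 1
    volume_cv: 10
  - kind: load
    volume_cv: 50
    collect_flowthrough: true
  - kind: wash
    buffer_port: 2
    volume_cv: 60
  - kind: elute
    buffer_port: 3
    volume_cv: 8
    fraction_size_cv: 1.0
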