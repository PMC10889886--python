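# Parallel IMAC purification on 5 mL columns: as the 1 mL variant but with
# a 200 CV load.  The 1000 mL load effluent cannot fit a 50 mL tube, so it
# is sent to post-column waste rather than captured.
name: histrap_5ml
description: His-tag IMAC purification, 5 mL column variant.
steps:
  - kind: equilibrate
    buffer_port: 1
    volume_cv: 10
  - kind: load
    volume_cv: 200
    collect_flowthrough: false
  - kind: wash
    buffer_port: 2
    volume_cv: 60
  - kind: elute
    buffer_port: 3
    volume_cv: 8
    fraction_size_cv: 1.0
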