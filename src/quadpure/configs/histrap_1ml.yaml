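# Four-channel IMAC rig: 1 mL HisTrap Excel columns, 1.5 mL fraction tubes.
name: histrap_1ml
description: >
  Four 1 mL HisTrap Excel columns for parallel IMAC purification of
  His-tagged proteins; collector plate holds ten rows of 1.5 mL tubes plus
  four rows of 50 mL flow-through tubes.
channels:
  - {column_volume_ml: 1.0, column_type: "HisTrap Excel 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HisTrap Excel 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HisTrap Excel 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HisTrap Excel 1 mL"}
buffer_labels:
  1: "equilibration: 20 mM sodium phosphate, 500 mM NaCl, pH 7.4"
  2: "wash: 20 mM sodium phosphate, 500 mM NaCl, 20 mM imidazole, pH 7.4"
  3: "elution: 20 mM sodium phosphate, 500 mM NaCl, 500 mM imidazole, pH 7.4"
plate:
  small_tube_ml: 1.5
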