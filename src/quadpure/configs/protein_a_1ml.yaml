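# Four-channel Protein A rig: 1 mL columns, low-pH elution into Tris prefill.
name: protein_a_1ml
description: >
  Four 1 mL Protein A columns for parallel antibody capture; fractions are
  eluted at low pH into tubes pre-loaded with neutralizing Tris.
channels:
  - {column_volume_ml: 1.0, column_type: "HiTrap Protein A HP 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HiTrap Protein A HP 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HiTrap Protein A HP 1 mL"}
  - {column_volume_ml: 1.0, column_type: "HiTrap Protein A HP 1 mL"}
buffer_labels:
  1: "equilibration/wash: 20 mM sodium phosphate, pH 7.0"
  2: "elution: 0.1 M citric acid, pH 3.0"
plate:
  small_tube_ml: 1.5
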