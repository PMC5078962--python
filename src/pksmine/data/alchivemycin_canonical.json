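{
  "_comment": "Canonical alchivemycin-type hybrid PKS/NRPS assembly line: a KSQ loading module (decarboxylated malonyl starter, C2), thirteen extension modules with methylmalonyl-CoA selection (YASHS) at modules 1, 4, 7, 10 and 11 and malonyl-CoA (HAFHS) elsewhere (module 2 carries the RAFHS one-off variant), beta-processing 3x KR, 5x DH/KR, 4x DH/ER/KR with one unprocessed module, and a terminal glycine-activating NRPS module; three monooxygenase ORFs and one cytochrome P450 ORF for tailoring. One module is split across two consecutive ORFs.",
  "modules": [
    {"kind": "pks_loading", "extender": "C2_malonyl"},
    {"kind": "pks_extension", "extender": "C3_methylmalonyl", "reduction_state": "double_bond", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "hydroxyl", "kr_type": "B_type", "at_motif": "RAFHS"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "saturated", "kr_type": "B_type", "er_config": "S_config"},
    {"kind": "pks_extension", "extender": "C3_methylmalonyl", "reduction_state": "double_bond", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "saturated", "kr_type": "B_type", "er_config": "S_config"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "double_bond", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C3_methylmalonyl", "reduction_state": "hydroxyl", "kr_type": "A_type"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "saturated", "kr_type": "B_type", "er_config": "R_config"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "double_bond", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C3_methylmalonyl", "reduction_state": "ketone"},
    {"kind": "pks_extension", "extender": "C3_methylmalonyl", "reduction_state": "hydroxyl", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "double_bond", "kr_type": "B_type"},
    {"kind": "pks_extension", "extender": "C2_malonyl", "reduction_state": "saturated", "kr_type": "B_type", "er_config": "S_config"},
    {"kind": "nrps", "extender": "amino_acid:glycine"}
  ],
  "orf_breaks": [[1, 0], [4, 0], [7, 0], [10, 0], [11, 2], [14, 0]],
  "tailoring": {"MONOOX": 3, "P450": 1},
  "seed": 20170867,
  "terminal_te": true
}
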