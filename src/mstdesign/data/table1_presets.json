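{
  "comment": "Literature uptake and transport parameters for EMT6/Ro-like tissue, minimum / typical / maximum literature spread. Units as printed in the column names; code converts to SI on load. Glucose diffusivities and the glucose saturation concentration are not part of the literature table: D values are standard aqueous-medium / tumour-tissue literature numbers, and glucose partitions 1:1 between medium and tissue (single aqueous phase), so its saturation concentration is set to the working concentration c0.",
  "cell_density_cells_per_uL": {
    "minimum": 2.1e5,
    "typical": 2.8e5,
    "maximum": 4.0e5
  },
  "glucose": {
    "q_max_mol_per_cell_s": {"minimum": 2.7e-18, "typical": 3.9e-17, "maximum": 2.5e-16},
    "k_M_mM": {"minimum": 4e-2, "typical": 4e-2, "maximum": 6e-2},
    "D_M_cm2_per_s": {"minimum": 6.7e-6, "typical": 6.7e-6, "maximum": 6.7e-6},
    "D_T_cm2_per_s": {"minimum": 1.1e-6, "typical": 1.1e-6, "maximum": 1.1e-6},
    "c0_mM": 11.0,
    "c_sat_M_mM": 11.0,
    "c_sat_T_mM": 11.0
  },
  "oxygen": {
    "q_max_mol_per_cell_s": {"minimum": 1.7e-18, "typical": 7.4e-17, "maximum": 7.0e-16},
    "k_M_mM": {"minimum": 4.6e-3, "typical": 4.63e-3, "maximum": 6.9e-3},
    "D_M_cm2_per_s": {"minimum": 2.0e-5, "typical": 2.44e-5, "maximum": 3.35e-5},
    "D_T_cm2_per_s": {"minimum": 9.5e-6, "typical": 1.85e-5, "maximum": 3.6e-5},
    "c0_mM": 0.21,
    "c_sat_M_mM": 0.21,
    "c_sat_T_mM": 1.02
  }
}
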