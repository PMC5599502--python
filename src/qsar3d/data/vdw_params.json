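{
  "scheme": "bondi-radii/amber-well-depths v1",
  "comment": "Per-element van der Waals radii (Angstrom, Bondi 1964 compilation), Lennard-Jones well depths (kcal/mol, generic force-field values for the dominant hybridization) and atom-based hydrophobicity increments (Ghose/Crippen-style sign conventions, coarse per-element).",
  "elements": {
    "H":  {"vdw_radius": 1.20, "well_depth": 0.0157, "hydrophobic": 0.10},
    "C":  {"vdw_radius": 1.70, "well_depth": 0.1094, "hydrophobic": 0.50},
    "N":  {"vdw_radius": 1.55, "well_depth": 0.1700, "hydrophobic": -0.40},
    "O":  {"vdw_radius": 1.52, "well_depth": 0.2100, "hydrophobic": -0.30},
    "F":  {"vdw_radius": 1.47, "well_depth": 0.0610, "hydrophobic": 0.30},
    "P":  {"vdw_radius": 1.80, "well_depth": 0.2000, "hydrophobic": 0.00},
    "S":  {"vdw_radius": 1.80, "well_depth": 0.2500, "hydrophobic": 0.40},
    "Cl": {"vdw_radius": 1.75, "well_depth": 0.2650, "hydrophobic": 0.70},
    "Br": {"vdw_radius": 1.85, "well_depth": 0.3200, "hydrophobic": 0.85},
    "I":  {"vdw_radius": 1.98, "well_depth": 0.4000, "hydrophobic": 1.00}
  },
  "probes": {
    "comfa_sp3_carbon": {"vdw_radius": 1.70, "well_depth": 0.1094, "charge": 1.0},
    "comsia_unit": {"vdw_radius": 1.0, "well_depth": 0.0, "charge": 1.0,
                    "comsia_props": [1.0, 1.0, 1.0, 1.0, 1.0]}
  }
}
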