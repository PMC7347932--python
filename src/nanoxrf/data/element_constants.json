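{
  "_comment": [
    "Nominal per-element constants for the fundamental-parameter factor",
    "f_X = sigma * xi / A used in thin-film calibration.",
    "sigma_cm2_g: approximate K fluorescence production cross-section at",
    "17 keV excitation (photoelectric K-shell cross-section times K",
    "fluorescence yield, order-of-magnitude values from standard X-ray",
    "data tables, rounded). xi: nominal silicon-drift-detector efficiency",
    "at the K-alpha energy (absorption of low-energy lines in windows and",
    "air paths). A_g_mol: standard atomic mass.",
    "These defaults are internally consistent placeholders suitable for",
    "round-trip analysis of synthetic data; replace sigma and xi with",
    "beamline-specific values for absolute quantification of real data."
  ],
  "elements": {
    "Si": {"sigma_cm2_g": 0.063, "xi": 0.25, "A_g_mol": 28.085},
    "P":  {"sigma_cm2_g": 0.105, "xi": 0.35, "A_g_mol": 30.974},
    "S":  {"sigma_cm2_g": 0.165, "xi": 0.45, "A_g_mol": 32.06},
    "Cl": {"sigma_cm2_g": 0.245, "xi": 0.55, "A_g_mol": 35.45},
    "K":  {"sigma_cm2_g": 0.52,  "xi": 0.70, "A_g_mol": 39.098},
    "Ca": {"sigma_cm2_g": 0.75,  "xi": 0.75, "A_g_mol": 40.078},
    "Fe": {"sigma_cm2_g": 9.9,   "xi": 0.92, "A_g_mol": 55.845},
    "Zn": {"sigma_cm2_g": 18.0,  "xi": 0.96, "A_g_mol": 65.38}
  }
}
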