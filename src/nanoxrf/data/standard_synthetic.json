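{
  "_comment": [
    "SYNTHETIC calibration-standard record. A real run measures a",
    "certified thin multilayer reference (known Fe areal mass with a",
    "certificate uncertainty) on its own Si3N4 mount; the certificate",
    "numbers are not public, so this file carries a self-consistent",
    "stand-in used by the phantom generator and the test-suite",
    "round-trips. am/eps in ng/cm^2; count rates are summed K-alpha",
    "counts per pixel-average on the standard; thicknesses in cm",
    "(sample mount 500 nm, standard mount 200 nm Si3N4)."
  ],
  "standard": {
    "am_fe_ng_cm2": 98.1,
    "eps_fe_ng_cm2": 12.8,
    "s_fe_counts": 5200.0,
    "s_si_counts": 41000.0,
    "t_si_cm": 5.0e-5,
    "t_si_std_cm": 2.0e-5
  }
}
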