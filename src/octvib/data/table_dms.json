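{
  "comment": "Direction-measurement orientations of the phantom study: polar angle theta from the reference optical axis and azimuth phi, degrees. Z is the reference (vertical) measurement; X and Y lie along the Cartesian axes.",
  "dms": [
    {"name": "A", "theta_deg": 40, "phi_deg": 0},
    {"name": "B", "theta_deg": 30, "phi_deg": 30},
    {"name": "C", "theta_deg": 20, "phi_deg": 60},
    {"name": "D", "theta_deg": 40, "phi_deg": 60},
    {"name": "E", "theta_deg": 10, "phi_deg": 90},
    {"name": "F", "theta_deg": 40, "phi_deg": 90},
    {"name": "X", "theta_deg": 90, "phi_deg": 0},
    {"name": "Y", "theta_deg": 90, "phi_deg": 90},
    {"name": "Z", "theta_deg": 0, "phi_deg": 0}
  ],
  "excluded_decompositions": ["ZCD", "ZEF"]
}
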