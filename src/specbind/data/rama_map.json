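{
  "version": 1,
  "comment": "Coarse four-level rectangle map over the (phi, psi) torus, degrees. Each box is [phi_min, phi_max, psi_min, psi_max]. Levels are checked core -> additional -> generous; anything uncovered is disallowed. GLY gets the default boxes plus their point-symmetric mirrors (glycine lacks a C-beta, so its map is symmetric under (phi,psi) -> (-phi,-psi)).",
  "default": {
    "core": [
      [-140, -40, -70, -10],
      [-170, -60, 100, 180],
      [-170, -60, -180, -170]
    ],
    "additional": [
      [-180, -20, -90, 10],
      [-180, -40, 60, 180],
      [-180, -40, -180, -160],
      [-90, -20, 120, 180]
    ],
    "generous": [
      [-180, 0, -110, 30],
      [-180, -20, 40, 180],
      [-180, -20, -180, -150]
    ]
  },
  "GLY": {
    "core": [
      [-140, -40, -70, -10],
      [-170, -60, 100, 180],
      [-170, -60, -180, -170],
      [40, 140, 10, 70],
      [60, 170, -180, -100],
      [60, 170, 170, 180]
    ],
    "additional": [
      [-180, -20, -90, 10],
      [-180, -40, 60, 180],
      [-180, -40, -180, -160],
      [-90, -20, 120, 180],
      [20, 180, -10, 90],
      [40, 180, -180, -60],
      [40, 180, 160, 180],
      [20, 90, -180, -120]
    ],
    "generous": [
      [-180, 0, -110, 30],
      [-180, -20, 40, 180],
      [-180, -20, -180, -150],
      [0, 180, -30, 110],
      [20, 180, -180, -40],
      [20, 180, 150, 180]
    ]
  }
}
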