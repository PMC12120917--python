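# Per-element constants for the image channels.
# Z: atomic number (dimensionless). ionization_energy: first ionization energy, eV,
# to 3 decimals (NIST ASD ground-state values, snapshot 2025).
symbol,Z,ionization_energy
H,1,13.598
C,6,11.260
N,7,14.534
O,8,13.618
F,9,17.423
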