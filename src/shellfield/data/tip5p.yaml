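# TIP5P rigid 5-site water model parameters (Mahoney & Jorgensen).
# Geometry in Å and degrees; charges in e; Lennard-Jones on the oxygen
# center only (sigma Å, epsilon kJ/mol).
name: TIP5P
geometry:
  r_oh: 0.9572
  hoh_angle: 104.52
  r_ol: 0.70
  lol_angle: 109.47
charges:
  H: 0.241
  L: -0.241
lennard_jones:
  sigma: 3.12
  epsilon: 0.66944
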