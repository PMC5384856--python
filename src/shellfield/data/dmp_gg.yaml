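# Dimethylphosphate anion (CH3O)2PO2−, gauche-gauche conformer.
#
# SYNTHETIC STAND-IN charge set: the electrostatic-potential-derived
# charges used in the original field simulations are not published, so
# this file ships a documented united-atom set constrained to net −1 e.
# Replace with your own charges for quantitative field magnitudes.
#
# Geometry is rebuilt from the internal coordinates below (Å, degrees);
# both methyl C-O-P-O dihedrals are +70° (gg conformer).  Lennard-Jones
# parameters (sigma Å, epsilon kJ/mol) are generic heavy-atom values for
# the water-solute repulsion, also stand-ins.
name: DMP-gg (stand-in charges)
internal_coordinates:
  r_po_free: 1.48       # P=O, free (anionic) oxygens O1, O2
  o_p_o_free_angle: 119.6
  r_po_ester: 1.60      # P-O, ester oxygens O3, O4
  o_p_o_ester_angle: 101.0
  r_oc: 1.42            # ester O - methyl C
  p_o_c_angle: 118.5
  c_o_p_o_dihedral: 70.0   # gauche; same sign on both sides -> gg
atoms:
  P:   {charge:  1.20, sigma: 3.83, epsilon: 2.40}
  O1:  {charge: -0.85, sigma: 3.03, epsilon: 0.50}
  O2:  {charge: -0.85, sigma: 3.03, epsilon: 0.50}
  O3:  {charge: -0.50, sigma: 2.93, epsilon: 0.42}
  O4:  {charge: -0.50, sigma: 2.93, epsilon: 0.42}
  C1:  {charge:  0.25, sigma: 3.67, epsilon: 0.80}   # united-atom CH3
  C2:  {charge:  0.25, sigma: 3.67, epsilon: 0.80}   # united-atom CH3
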